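"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the *statistical structure* the analysis consumes,
not the sensors that produced the real data:

* a tree-cover field whose distribution conditional on a climate driver is
  a two-component Gaussian mixture — savanna-only on the dry side of the
  bistability range, forest-only on the wet side, a weighted mixture in
  between (cross-sectional data cannot distinguish a mixture from true
  hysteresis, and the potential analysis only needs conditional
  bimodality);
* monthly precipitation/temperature cubes with injected linear trends and
  truncated-Gaussian noise, with the injected slopes returned as ground
  truth for recovery tests;
* disturbance layers: per-pixel drought-event counts (binomial, 0–5),
  random-walk road polylines with a rasterised proximity layer, and
  smooth-field protection / deforestation masks hitting target areal
  fractions;
* steady forcing bundles (wind, evaporation, precipitation, precipitable
  water) for the moisture tracker.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .climate import MonthlyClimateCube
from .grids import GridDescriptor

__all__ = [
    "SyntheticBiomeConfig",
    "SyntheticClimateConfig",
    "SyntheticDisturbanceConfig",
    "DisturbanceLayers",
    "MoistureForcing",
    "generate_axis_field",
    "generate_tree_cover",
    "generate_climate_cube",
    "generate_disturbances",
    "generate_moisture_forcing",
]

#: default seasonal monthly rainfall profile (mm), annual total 2000 mm —
#: a wet-season/dry-season cycle typical of the southern Amazon
DEFAULT_MONTHLY_CLIMATOLOGY = (
    280.0, 260.0, 250.0, 200.0, 120.0, 60.0,
    40.0, 50.0, 80.0, 160.0, 230.0, 270.0,
)

_AXIS_PRESETS = {
    # axis -> (axis_range, lower_threshold, upper_threshold, drier_is_high)
    "map": ((200.0, 3000.0), 1000.0, 1800.0, False),
    "mcwd": ((-800.0, 0.0), -450.0, -350.0, False),
    "dsl": ((0.0, 12.0), 5.0, 8.0, True),
}


@dataclass(frozen=True)
class SyntheticBiomeConfig:
    """Bimodal-tree-cover biome conditioned on a climate driver.

    Defaults encode the annual-rainfall case: only the low-tree-cover
    (savanna) mode below 1000 mm yr⁻¹, only the high (forest) mode above
    1800 mm yr⁻¹, and a mixture with ``bistable_forest_weight`` forest
    probability in between. Mode standard deviations are chosen so the two
    modes stay separable under the 0.005 density floor at a few thousand
    pixels per window.
    """

    grid_shape: tuple[int, int] = (250, 400)  # 1e5 pixels
    pixel_size: float = 0.05
    axis: str = "map"
    axis_range: tuple[float, float] = (200.0, 3000.0)
    true_lower_threshold: float = 1000.0
    true_upper_threshold: float = 1800.0
    drier_is_high: bool = False
    forest_mode_mean: float = 85.0
    forest_mode_sd: float = 8.0
    savanna_mode_mean: float = 20.0
    savanna_mode_sd: float = 10.0
    bistable_forest_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_lower_threshold >= self.true_upper_threshold:
            raise ValueError("true_lower_threshold must be < true_upper_threshold")
        if not (0 <= self.savanna_mode_mean < self.forest_mode_mean <= 100):
            raise ValueError("mode means must satisfy 0 <= savanna < forest <= 100")
        if not 0 <= self.bistable_forest_weight <= 1:
            raise ValueError("bistable_forest_weight must be in [0, 1]")
        lo, hi = self.axis_range
        if not (lo < self.true_lower_threshold and self.true_upper_threshold < hi):
            raise ValueError(
                "thresholds must lie strictly inside axis_range "
                "(no bistable zone representable otherwise)"
            )

    @classmethod
    def for_axis(cls, axis: str, **overrides) -> "SyntheticBiomeConfig":
        """Preset configs for the map / mcwd / dsl driver axes."""
        if axis not in _AXIS_PRESETS:
            raise ValueError(f"unknown axis {axis!r}")
        rng, lo, hi, drier_high = _AXIS_PRESETS[axis]
        kw = dict(
            axis=axis,
            axis_range=rng,
            true_lower_threshold=lo,
            true_upper_threshold=hi,
            drier_is_high=drier_high,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def grid(self) -> GridDescriptor:
        return GridDescriptor(
            rows=self.grid_shape[0], cols=self.grid_shape[1], pixel_size=self.pixel_size
        )

    def ground_truth(self) -> dict:
        return asdict(self)


def generate_axis_field(cfg: SyntheticBiomeConfig) -> np.ndarray:
    """Continuous climate-driver field spanning ``axis_range`` across the grid.

    A west–east gradient plus uniform sub-column jitter, so every driver
    window pools pixels from a narrow strip of columns. The field is the
    conditioning variable for :func:`generate_tree_cover` and stands in for
    the corresponding observed climate metric.
    """
    rows, cols = cfg.grid_shape
    if rows * cols == 0:
        raise ValueError("degenerate grid with 0 pixels")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.axis_range
    col_step = (hi - lo) / cols
    base = lo + (np.arange(cols) + 0.5) * col_step
    fieldv = np.broadcast_to(base, (rows, cols)).copy()
    fieldv += rng.uniform(-col_step / 2, col_step / 2, size=(rows, cols))
    return np.clip(fieldv, lo, hi)


def generate_tree_cover(
    cfg: SyntheticBiomeConfig, axis_field: np.ndarray | None = None
) -> np.ndarray:
    """Tree-cover raster (%) drawn from the climate-conditional mixture.

    Savanna mode where the driver is on the dry side of the lower
    threshold, forest mode on the wet side of the upper threshold, and a
    ``bistable_forest_weight`` mixture in between. Values are clipped to
    [0, 100]. Deterministic for a fixed config seed.
    """
    if axis_field is None:
        axis_field = generate_axis_field(cfg)
    axis_field = np.asarray(axis_field, dtype=float)
    if axis_field.shape != cfg.grid_shape:
        raise ValueError("axis field does not match the configured grid")
    if not np.all(np.isfinite(axis_field)):
        raise ValueError("axis field must be finite")
    if axis_field.size == 0:
        raise ValueError("degenerate grid with 0 pixels")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if cfg.drier_is_high:
        savanna_only = axis_field > cfg.true_upper_threshold
        forest_only = axis_field < cfg.true_lower_threshold
    else:
        savanna_only = axis_field < cfg.true_lower_threshold
        forest_only = axis_field > cfg.true_upper_threshold
    bistable = ~(savanna_only | forest_only)
    is_forest = forest_only | (
        bistable & (rng.random(axis_field.shape) < cfg.bistable_forest_weight)
    )
    draws = np.where(
        is_forest,
        rng.normal(cfg.forest_mode_mean, cfg.forest_mode_sd, axis_field.shape),
        rng.normal(cfg.savanna_mode_mean, cfg.savanna_mode_sd, axis_field.shape),
    )
    return np.clip(draws, 0.0, 100.0)


@dataclass(frozen=True)
class SyntheticClimateConfig:
    """Monthly precipitation/temperature cube with injected linear trends.

    The default injected temperature trend is 0.027 °C yr⁻¹ (0.27 °C per
    decade), the observed mean dry-season warming rate over 1981–2020 that
    the trend-recovery tests must reproduce.
    """

    years: tuple[int, int] = (1981, 2020)
    monthly_precip_climatology: tuple[float, ...] = DEFAULT_MONTHLY_CLIMATOLOGY
    precip_trend: float = 0.0  # mm yr⁻¹ per year, applied to the annual total
    temp_base: float = 26.0  # °C
    temp_trend: float = 0.027  # °C yr⁻¹
    noise_sd_precip: float = 15.0  # mm, per month
    noise_sd_temp: float = 0.15  # °C, per month
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years[1] - self.years[0] + 1 < 3:
            raise ValueError("need at least 3 years for trend regression")
        if len(self.monthly_precip_climatology) != 12:
            raise ValueError("climatology needs 12 monthly values")
        if any(v < 0 for v in self.monthly_precip_climatology):
            raise ValueError("negative climatology")


def generate_climate_cube(
    cfg: SyntheticClimateConfig,
    grid: GridDescriptor,
    precip_scale: np.ndarray | None = None,
) -> tuple[MonthlyClimateCube, MonthlyClimateCube, dict]:
    """Precipitation and temperature cubes plus a ground-truth record.

    Each pixel's monthly value is climatology (optionally scaled per pixel
    by ``precip_scale`` to span a rainfall gradient) + a year-indexed trend
    + Gaussian noise; precipitation is truncated at zero. The returned
    ground truth holds the injected slopes for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    y0, y1 = cfg.years
    years = np.arange(y0, y1 + 1)
    ny = years.size
    t = (years - y0)[:, None, None, None]  # years since start
    clim = np.asarray(cfg.monthly_precip_climatology)[None, :, None, None]
    scale = (
        np.ones(grid.shape) if precip_scale is None else np.asarray(precip_scale, float)
    )[None, None, :, :]
    precip = clim * scale + cfg.precip_trend / 12.0 * t
    if cfg.noise_sd_precip > 0:
        precip = precip + rng.normal(0, cfg.noise_sd_precip, precip.shape)
    precip = np.maximum(np.broadcast_to(precip, (ny, 12) + grid.shape), 0.0)

    temp = cfg.temp_base + cfg.temp_trend * t + np.zeros((ny, 12) + grid.shape)
    if cfg.noise_sd_temp > 0:
        temp = temp + rng.normal(0, cfg.noise_sd_temp, temp.shape)

    truth = {
        "precip_trend": cfg.precip_trend,
        "temp_trend": cfg.temp_trend,
        "temp_base": cfg.temp_base,
        "years": (y0, y1),
    }
    return (
        MonthlyClimateCube(precip.copy(), years, grid),
        MonthlyClimateCube(temp, years, grid),
        truth,
    )


@dataclass(frozen=True)
class SyntheticDisturbanceConfig:
    """Disturbance layers: droughts, roads, protection, deforestation."""

    n_roads: int = 5
    road_waypoints: int = 25
    road_step_deg: float = 0.6
    protected_fraction: float = 0.3
    deforested_fraction: float = 0.15
    drought_lambda: float = 1.5  # mean per-pixel drought-event count, 0–5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("protected_fraction", "deforested_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.protected_fraction + self.deforested_fraction > 1:
            raise ValueError("protected + deforested fractions exceed 1")
        if not 0 <= self.drought_lambda <= 5:
            raise ValueError("drought_lambda must be in [0, 5]")


@dataclass
class DisturbanceLayers:
    """Generated disturbance stack components on a shared grid."""

    grid: GridDescriptor
    drought_counts: np.ndarray  # int, 0–5
    roads: list  # shapely LineStrings (lon/lat)
    road_near: np.ndarray  # bool, within buffer of a road
    protected: np.ndarray  # bool
    deforested: np.ndarray  # bool


def _fraction_mask(rng: np.random.Generator, grid: GridDescriptor, fraction: float) -> np.ndarray:
    """Spatially smooth boolean mask hitting the target areal fraction."""
    if fraction <= 0:
        return np.zeros(grid.shape, dtype=bool)
    if fraction >= 1:
        return np.ones(grid.shape, dtype=bool)
    noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=max(2.0, min(grid.shape) / 20))
    cut = np.quantile(smooth, 1.0 - fraction)
    return smooth > cut


def _random_walk_road(rng: np.random.Generator, grid: GridDescriptor, cfg) -> "object":
    """Random-walk polyline inside the grid (only distance-to-road matters)."""
    from shapely.geometry import LineString

    lon_lo = grid.origin_lon
    lon_hi = grid.origin_lon + grid.cols * grid.pixel_size
    lat_hi = grid.origin_lat
    lat_lo = grid.origin_lat - grid.rows * grid.pixel_size
    lon = rng.uniform(lon_lo, lon_hi)
    lat = rng.uniform(lat_lo, lat_hi)
    heading = rng.uniform(0, 2 * np.pi)
    coords = [(lon, lat)]
    for _ in range(cfg.road_waypoints - 1):
        heading += rng.normal(0, 0.4)
        lon = np.clip(lon + cfg.road_step_deg * np.cos(heading), lon_lo, lon_hi)
        lat = np.clip(lat + cfg.road_step_deg * np.sin(heading), lat_lo, lat_hi)
        coords.append((lon, lat))
    return LineString(coords)


def generate_disturbances(
    cfg: SyntheticDisturbanceConfig, grid: GridDescriptor, road_buffer_km: float = 10.0
) -> DisturbanceLayers:
    """Drought counts, road network + proximity, protection and deforestation.

    Drought counts are Binomial(5, λ/5) per pixel — integer support 0–5
    with mean λ. Mask fractions are hit by quantile-thresholding a smoothed
    noise field, so realised areal fractions match targets to well within
    ±2 % on grids of 10⁴ pixels or more.
    """
    from .transition import road_proximity

    rng = np.random.default_rng(cfg.seed)
    drought = rng.binomial(5, cfg.drought_lambda / 5.0, size=grid.shape)
    roads = [_random_walk_road(rng, grid, cfg) for _ in range(cfg.n_roads)]
    road_near = road_proximity(roads, grid, buffer_km=road_buffer_km)
    protected = _fraction_mask(rng, grid, cfg.protected_fraction)
    # carve deforestation out of the unprotected complement so the two
    # masks never overlap (fractions validated to sum <= 1)
    if cfg.deforested_fraction > 0:
        noise = rng.standard_normal(grid.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=max(2.0, min(grid.shape) / 20))
        smooth[protected] = -np.inf
        k = int(round(cfg.deforested_fraction * grid.n_pixels))
        if k > 0:
            cut = np.partition(smooth.ravel(), -k)[-k]
            deforested = smooth >= cut
        else:
            deforested = np.zeros(grid.shape, dtype=bool)
    else:
        deforested = np.zeros(grid.shape, dtype=bool)
    return DisturbanceLayers(
        grid=grid,
        drought_counts=drought.astype(int),
        roads=roads,
        road_near=road_near,
        protected=protected,
        deforested=deforested,
    )


@dataclass
class MoistureForcing:
    """Steady forcing bundle for the moisture tracker (single layer)."""

    grid: GridDescriptor
    wind_u: np.ndarray  # m s⁻¹, eastward
    wind_v: np.ndarray  # m s⁻¹, northward
    evap: np.ndarray  # mm month⁻¹
    precip: np.ndarray  # mm month⁻¹
    tpw: np.ndarray  # mm precipitable water


def generate_moisture_forcing(
    grid: GridDescriptor,
    wind_u: float | np.ndarray = 5.0,
    wind_v: float | np.ndarray = 0.0,
    evap: float | np.ndarray = 3.0,
    precip: float | np.ndarray = 100.0,
    tpw: float | np.ndarray = 40.0,
) -> MoistureForcing:
    """Broadcast scalar or gridded forcing onto the simulation grid."""
    def expand(v):
        arr = np.broadcast_to(np.asarray(v, dtype=float), grid.shape).copy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("forcing fields must be finite")
        return arr

    u, v, e, p, w = (expand(x) for x in (wind_u, wind_v, evap, precip, tpw))
    if np.any(e < 0) or np.any(p < 0):
        raise ValueError("evaporation and precipitation must be non-negative")
    if np.any((p > 0) & (w <= 0)):
        raise ValueError("precipitable water must be positive wherever it rains")
    return MoistureForcing(grid=grid, wind_u=u, wind_v=v, evap=e, precip=p, tpw=w)
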