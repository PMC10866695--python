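"""Per-pixel climate water-stress metrics and trend screening.

Implements the standard metrics used to condition tropical tree-cover
distributions on climate:

* **MAP** — mean annual precipitation (mm yr⁻¹), the mean over years of the
  annual sums.
* **MCWD** — maximum cumulative water deficit (mm, ≤ 0): the most negative
  value of the month-by-month running deficit ``WDₙ = min(0, WDₙ₋₁ + Pₙ − E)``
  within a year, with a fixed reference evapotranspiration E (100 mm month⁻¹
  by convention). More negative = more intense seasonal drought.
* **DSL** — dry-season length (months): the number of climatological months
  with precipitation strictly below a dry-month threshold (100 mm by the
  usual tropical convention).
* **dry-season temperature** — per-year mean over July–October.

Trend screening fits per-pixel ordinary least squares of a yearly series
against calendar year and keeps slopes significant at a two-sided ``p < α``
(α = 0.1 by default). Significant rainfall trends can be extrapolated to
2050 by evaluating the fitted line at that year. Extreme-drought events are
years whose annual MCWD drops at least ``anomaly_sd`` standard deviations
below the historical mean, counted per pixel and capped at 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import GridDescriptor, check_same_grid

__all__ = [
    "MonthlyClimateCube",
    "ClimateMetricMap",
    "TrendMap",
    "DroughtConfig",
    "compute_map",
    "mcwd_annual",
    "compute_mcwd",
    "compute_dsl",
    "dry_season_temperature",
    "fit_trend",
    "extrapolate_to_2050",
    "detect_drought_events",
]

#: July–October, 0-based month indices
DRY_SEASON_MONTHS = (6, 7, 8, 9)


@dataclass
class MonthlyClimateCube:
    """Monthly gridded series: ``values`` shaped (n_years, 12, rows, cols)."""

    values: np.ndarray
    years: np.ndarray
    grid: GridDescriptor
    mask: np.ndarray | None = None  # True = valid pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim != 4 or self.values.shape[1] != 12:
            raise ValueError(
                f"cube must be (n_years, 12, rows, cols); got {self.values.shape}"
            )
        if self.values.shape[0] != self.years.size:
            raise ValueError("year axis length disagrees with year labels")
        if self.values.shape[2:] != self.grid.shape:
            raise ValueError("cube spatial shape disagrees with grid")
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)

    @property
    def n_years(self) -> int:
        return self.years.size


@dataclass
class ClimateMetricMap:
    """A single per-pixel climate metric field (NaN where masked)."""

    metric: str  # 'map' | 'mcwd' | 'dsl' | 'dry_season_temp'
    values: np.ndarray
    grid: GridDescriptor
    reference_period: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("metric shape disagrees with grid")


@dataclass
class TrendMap:
    """Per-pixel OLS trend of a yearly series against calendar year."""

    slope: np.ndarray  # units yr⁻¹
    intercept: np.ndarray  # units at year 0 (calendar)
    p_value: np.ndarray
    significant: np.ndarray  # p < alpha
    alpha: float
    grid: GridDescriptor


@dataclass
class DroughtConfig:
    """Extreme-drought detection settings (2-sd MCWD anomalies, 2001–2018)."""

    window_years: tuple[int, int] = (2001, 2018)
    anomaly_sd: float = 2.0
    reference_mean: np.ndarray | float | None = None
    reference_sd: np.ndarray | float | None = None
    max_events: int = 5

    def __post_init__(self) -> None:
        if self.anomaly_sd <= 0:
            raise ValueError("anomaly_sd must be positive")


def _apply_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    out[..., ~mask] = np.nan
    return out


def compute_map(precip: MonthlyClimateCube) -> ClimateMetricMap:
    """Mean annual precipitation: mean over years of the annual sums."""
    if precip.n_years < 1:
        raise ValueError("need at least one complete year")
    annual = precip.values.sum(axis=1)  # (n_years, rows, cols)
    values = _apply_mask(annual.mean(axis=0), precip.mask)
    return ClimateMetricMap(
        "map", values, precip.grid, (int(precip.years[0]), int(precip.years[-1]))
    )


def mcwd_annual(precip: MonthlyClimateCube, evap_ref: float = 100.0) -> np.ndarray:
    """Per-year MCWD series, shape (n_years, rows, cols), all values ≤ 0.

    The running deficit restarts at zero each January:
    ``WD₁ = min(0, P₁ − E)``, ``WDₙ = min(0, WDₙ₋₁ + Pₙ − E)``; the year's
    MCWD is the most negative monthly value.
    """
    if evap_ref < 0:
        raise ValueError("reference evapotranspiration must be non-negative")
    p = precip.values
    wd = np.zeros((p.shape[0],) + p.shape[2:])  # (n_years, rows, cols)
    mcwd = np.zeros_like(wd)
    for m in range(12):
        wd = np.minimum(0.0, wd + p[:, m] - evap_ref)
        mcwd = np.minimum(mcwd, wd)
    return mcwd


def compute_mcwd(precip: MonthlyClimateCube, evap_ref: float = 100.0) -> ClimateMetricMap:
    """Climatological MCWD: mean over years of the annual MCWD."""
    values = _apply_mask(mcwd_annual(precip, evap_ref).mean(axis=0), precip.mask)
    return ClimateMetricMap(
        "mcwd", values, precip.grid, (int(precip.years[0]), int(precip.years[-1]))
    )


def compute_dsl(precip: MonthlyClimateCube, dry_month_threshold: float = 100.0) -> ClimateMetricMap:
    """Dry-season length: climatological months strictly below the threshold."""
    climatology = precip.values.mean(axis=0)  # (12, rows, cols)
    values = (climatology < dry_month_threshold).sum(axis=0).astype(float)
    values = _apply_mask(values, precip.mask)
    return ClimateMetricMap(
        "dsl", values, precip.grid, (int(precip.years[0]), int(precip.years[-1]))
    )


def dry_season_temperature(
    temp: MonthlyClimateCube, months: tuple[int, ...] = DRY_SEASON_MONTHS
) -> np.ndarray:
    """Per-year dry-season (July–October) mean temperature, (n_years, rows, cols)."""
    sel = temp.values[:, list(months)]
    out = sel.mean(axis=1)
    out[:, ~temp.mask] = np.nan
    return out


def fit_trend(
    series: np.ndarray,
    years: np.ndarray,
    grid: GridDescriptor | None = None,
    alpha: float = 0.1,
) -> TrendMap:
    """Per-pixel OLS of a yearly series against calendar year.

    ``series`` is (n_years, rows, cols) (or (n_years,) for a single pixel,
    returned on a 1×1 grid). Pixels with fewer than 3 finite years are
    masked (NaN slope, not significant); pixels with zero variance in y get
    slope 0 and an undefined p-value (NaN, not significant). A perfect
    noise-free fit yields p = 0.
    """
    series = np.asarray(series, dtype=float)
    years = np.asarray(years, dtype=float)
    single = series.ndim == 1
    if single:
        series = series[:, None, None]
    if grid is None:
        grid = GridDescriptor(rows=series.shape[1], cols=series.shape[2])
    x = years[:, None, None]
    w = np.isfinite(series)
    y = np.where(w, series, 0.0)
    n = w.sum(axis=0)
    sx = (w * x).sum(axis=0)
    sy = y.sum(axis=0)
    sxx = (w * x**2).sum(axis=0)
    sxy = (w * x * y).sum(axis=0)
    syy = (y**2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx**2
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n
        syy_c = syy - sy**2 / n  # total SS of y about its mean
        sse = np.maximum(syy - intercept * sy - slope * sxy, 0.0)
        sxx_c = (denom / n)
        se = np.sqrt(sse / np.maximum(n - 2, 1) / sxx_c)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    # perfect fits: se == 0 with non-trivial slope -> p = 0
    p = np.where((se == 0) & np.isfinite(slope) & (slope != 0), 0.0, p)

    usable = (n >= 3) & (denom > 0)
    # zero variance in y: slope exactly 0, p undefined
    flat = usable & np.isclose(syy_c, 0.0, atol=1e-10 * np.maximum(np.abs(syy), 1.0))
    slope = np.where(flat, 0.0, slope)
    intercept = np.where(flat, sy / np.maximum(n, 1), intercept)
    p = np.where(flat, np.nan, p)
    slope = np.where(usable, slope, np.nan)
    intercept = np.where(usable, intercept, np.nan)
    p = np.where(usable, p, np.nan)
    significant = np.where(np.isfinite(p), p < alpha, False)
    if single:
        return TrendMap(slope, intercept, p, significant, alpha, grid)
    return TrendMap(slope, intercept, p, significant, alpha, grid)


def extrapolate_to_2050(
    trend: TrendMap,
    base_metric: ClimateMetricMap,
    target_year: int = 2050,
    slope_bound: float = 25.0,
) -> ClimateMetricMap:
    """Evaluate the fitted regression line at ``target_year`` where significant.

    Pixels without a significant trend keep the base metric unchanged. A
    sanity guard rejects any fitted |slope| above ``slope_bound`` (units
    yr⁻¹) as physically implausible.
    """
    check_same_grid(trend.grid, base_metric.grid)
    finite = np.isfinite(trend.slope)
    if np.any(np.abs(trend.slope[finite]) > slope_bound):
        worst = np.nanmax(np.abs(trend.slope))
        raise ValueError(
            f"trend magnitude guard: |slope| up to {worst:.3g} exceeds bound {slope_bound}"
        )
    projected = trend.intercept + trend.slope * target_year
    values = np.where(trend.significant, projected, base_metric.values)
    return ClimateMetricMap(base_metric.metric, values, base_metric.grid, None)


def detect_drought_events(
    mcwd_series: np.ndarray,
    cfg: DroughtConfig | None = None,
    years: np.ndarray | None = None,
) -> np.ndarray:
    """Count extreme-drought years per pixel from an annual MCWD series.

    An event is a year whose MCWD is at least ``anomaly_sd`` standard
    deviations *below* (more negative than) the reference mean. The
    reference mean/sd default to the series itself; counts are capped at
    ``max_events``. Zero-sd pixels report 0 events.
    """
    cfg = cfg or DroughtConfig()
    series = np.asarray(mcwd_series, dtype=float)
    if years is not None:
        years = np.asarray(years)
        lo, hi = cfg.window_years
        sel = (years >= lo) & (years <= hi)
        series = series[sel]
    if series.shape[0] < 5:
        raise ValueError("need at least 5 years of MCWD for drought detection")
    mean = cfg.reference_mean if cfg.reference_mean is not None else series.mean(axis=0)
    sd = cfg.reference_sd if cfg.reference_sd is not None else series.std(axis=0, ddof=1)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(invalid="ignore"):
        events = (series <= mean - cfg.anomaly_sd * sd).sum(axis=0)
    events = np.where(sd > 0, events, 0)
    return np.minimum(events, cfg.max_events).astype(int)
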