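"""Additive ecosystem transition-potential index and safe-boundary flags.

The index compounds five per-pixel disturbance layers by simple addition:

====================================  =========================================
layer                                 contribution
====================================  =========================================
dry-season warming trend              10 × slope (°C yr⁻¹), significant only
2050 stability class                  0 forest / +1 bistable / +2 savanna
repeated extreme droughts             +0.2 per event (0–5 events)
road proximity                        +1 within 10 km of a road
protected area / Indigenous territory −1 inside
====================================  =========================================

Accumulated deforestation and savanna biome are excluded (masked) before
summation. With observed warming slopes in [−0.01, 0.06] °C yr⁻¹ the index
spans −1.1 to 4.6; the canonical no-trend extremes are −1 (protected,
undisturbed stable forest) and 4 (unprotected stable savanna with five
droughts and a road).

Safe boundaries keep each water-stress driver conservatively short of its
critical threshold: 1800 mm annual rainfall, −350 mm MCWD, 5 months DSL and
10 % accumulated deforestation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import TrendMap
from .grids import GridDescriptor, check_same_grid
from .stability import StabilityClassMap, CLASS_MASKED

__all__ = [
    "EARTH_RADIUS_KM",
    "TransitionPotentialConfig",
    "DisturbanceStack",
    "TransitionPotentialMap",
    "road_proximity",
    "compute_transition_potential",
    "categorize_tp",
    "safe_boundary_report",
    "SAFE_BOUNDARIES",
]

EARTH_RADIUS_KM = 6371.0088

#: safe boundary per driver: (boundary value, safe side: +1 = larger is safe)
SAFE_BOUNDARIES = {
    "annual_rainfall_mm": (1800.0, +1),
    "mcwd_mm": (-350.0, +1),
    "dsl_months": (5.0, -1),
    "deforested_fraction": (0.10, -1),
}


@dataclass(frozen=True)
class TransitionPotentialConfig:
    """Index constants; defaults are the standard additive weights."""

    temp_slope_factor: float = 10.0
    class_scores: tuple[float, float, float] = (0.0, 1.0, 2.0)  # forest, bistable, savanna
    drought_weight: float = 0.2
    road_buffer_km: float = 10.0
    road_score: float = 1.0
    governance_score: float = -1.0
    category_rule: str = "text"  # 'text': low<=1<moderate<=2<high; 'figure': <0 / 1–2 / >2

    def __post_init__(self) -> None:
        if self.road_buffer_km <= 0:
            raise ValueError("road buffer must be positive")
        if self.category_rule not in ("text", "figure"):
            raise ValueError("category_rule must be 'text' or 'figure'")


@dataclass
class DisturbanceStack:
    """Grid-aligned inputs of the transition-potential index."""

    temp_trend: TrendMap
    stability_2050: StabilityClassMap
    drought_counts: np.ndarray
    road_near: np.ndarray
    protected: np.ndarray
    deforested: np.ndarray
    savanna_biome: np.ndarray
    grid: GridDescriptor

    def validate(self) -> None:
        layers = {
            "temp_trend": self.temp_trend,
            "stability_2050": self.stability_2050,
            "drought_counts": self.drought_counts,
            "road_near": self.road_near,
            "protected": self.protected,
            "deforested": self.deforested,
            "savanna_biome": self.savanna_biome,
        }
        for name, layer in layers.items():
            if layer is None:
                raise ValueError(f"missing disturbance layer: {name}")
        check_same_grid(self.grid, self.temp_trend.grid, self.stability_2050.grid)
        for name in ("drought_counts", "road_near", "protected", "deforested", "savanna_biome"):
            arr = np.asarray(layers[name])
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name} shape {arr.shape} != grid {self.grid.shape}")
        dc = np.asarray(self.drought_counts)
        if dc.min() < 0 or dc.max() > 5:
            raise ValueError("drought counts must be integers in [0, 5]")


@dataclass
class TransitionPotentialMap:
    """Per-pixel index (NaN outside the analysis mask) plus categories."""

    tp: np.ndarray
    grid: GridDescriptor
    category: np.ndarray | None = None  # int8: 0 low, 1 moderate, 2 high, -1 out
    area_fractions: pd.Series | None = None


def _great_circle_segment_distance_km(
    lon: np.ndarray, lat: np.ndarray, a: tuple[float, float], b: tuple[float, float]
) -> np.ndarray:
    """Great-circle distance (km) from points to the geodesic segment a–b."""
    def unit(lo, la):
        lo, la = np.radians(lo), np.radians(la)
        return np.stack(
            [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1
        )

    p = unit(lon, lat)  # (..., 3)
    va, vb = unit(*a), unit(*b)
    axb = np.cross(va, vb)
    norm = np.linalg.norm(axb)
    if norm < 1e-15:  # degenerate segment: treat as the point a
        return np.arccos(np.clip(p @ va, -1, 1)) * EARTH_RADIUS_KM
    n = axb / norm
    # cross-track angle from the full great circle
    sin_xt = np.clip(p @ n, -1.0, 1.0)
    # foot of the perpendicular on the great circle
    f = p - sin_xt[..., None] * n
    f /= np.linalg.norm(f, axis=-1, keepdims=True)
    # is the foot inside the arc a->b?
    ang_ab = np.arccos(np.clip(va @ vb, -1, 1))
    ang_af = np.arccos(np.clip(f @ va, -1, 1))
    ang_fb = np.arccos(np.clip(f @ vb, -1, 1))
    inside = np.abs(ang_af + ang_fb - ang_ab) < 1e-6
    d_arc = np.abs(np.arcsin(sin_xt))
    d_a = np.arccos(np.clip(p @ va, -1, 1))
    d_b = np.arccos(np.clip(p @ vb, -1, 1))
    return np.where(inside, d_arc, np.minimum(d_a, d_b)) * EARTH_RADIUS_KM


def road_proximity(roads, grid: GridDescriptor, buffer_km: float = 10.0) -> np.ndarray:
    """Boolean raster: pixel centre within ``buffer_km`` of any road segment.

    Distances are great-circle from pixel centres to geodesic segments
    (boundary inclusive). An empty road set yields all-False.
    """
    lon, lat = grid.centers()
    near = np.zeros(grid.shape, dtype=bool)
    todo = ~near
    for road in roads:
        coords = list(road.coords) if hasattr(road, "coords") else list(road)
        for a, b in zip(coords[:-1], coords[1:]):
            idx = np.nonzero(todo)
            if idx[0].size == 0:
                return near
            d = _great_circle_segment_distance_km(lon[idx], lat[idx], a, b)
            hit = d <= buffer_km
            near[idx[0][hit], idx[1][hit]] = True
            todo[idx[0][hit], idx[1][hit]] = False
    return near


def compute_transition_potential(
    stack: DisturbanceStack, cfg: TransitionPotentialConfig | None = None
) -> TransitionPotentialMap:
    """Sum the five disturbance layers into the transition-potential index.

    Non-significant temperature slopes contribute 0. Pixels that are
    deforested, savanna biome, or masked in the 2050 class map are NaN.
    The sum is order-free by construction (pure addition).
    """
    cfg = cfg or TransitionPotentialConfig()
    stack.validate()
    trend = stack.temp_trend
    slope_term = np.where(
        trend.significant & np.isfinite(trend.slope), trend.slope, 0.0
    ) * cfg.temp_slope_factor
    cls = stack.stability_2050.values
    score_lut = np.asarray(cfg.class_scores)
    class_term = np.where(cls == CLASS_MASKED, np.nan, score_lut[np.clip(cls, 0, 2)])
    tp = (
        slope_term
        + class_term
        + cfg.drought_weight * np.asarray(stack.drought_counts, dtype=float)
        + cfg.road_score * np.asarray(stack.road_near, dtype=float)
        + cfg.governance_score * np.asarray(stack.protected, dtype=float)
    )
    excluded = np.asarray(stack.deforested, bool) | np.asarray(stack.savanna_biome, bool)
    tp = np.where(excluded, np.nan, tp)
    return TransitionPotentialMap(tp=tp, grid=stack.grid)


CATEGORY_NAMES = {0: "low", 1: "moderate", 2: "high", -1: "excluded"}


def categorize_tp(
    tp_map: TransitionPotentialMap, cfg: TransitionPotentialConfig | None = None
) -> TransitionPotentialMap:
    """Bin the index into low / moderate / high and report area fractions.

    The default ('text') rule uses half-open upward breaks at 1 and 2:
    low ≤ 1 < moderate ≤ 2 < high, matching the cumulative "more than 1 /
    more than 2 disturbance types" reading. The alternative 'figure' rule
    (< 0 low, 1–2 moderate, > 2 high) leaves [0, 1) unlabelled and is kept
    for comparison. Fractions are over the analysis mask and include a
    cumulative ``moderate_or_high`` entry.
    """
    cfg = cfg or TransitionPotentialConfig()
    tp = tp_map.tp
    cat = np.full(tp.shape, -1, dtype=np.int8)
    ok = np.isfinite(tp)
    if cfg.category_rule == "text":
        cat[ok & (tp <= 1)] = 0
        cat[ok & (tp > 1) & (tp <= 2)] = 1
        cat[ok & (tp > 2)] = 2
    else:  # figure caption rule
        cat[ok & (tp < 0)] = 0
        cat[ok & (tp >= 1) & (tp <= 2)] = 1
        cat[ok & (tp > 2)] = 2
    n_ok = int(ok.sum())
    fracs = {}
    for code, name in ((0, "low"), (1, "moderate"), (2, "high")):
        fracs[name] = float(np.sum(cat == code)) / n_ok if n_ok else np.nan
    fracs["moderate_or_high"] = fracs["moderate"] + fracs["high"]
    return TransitionPotentialMap(
        tp=tp, grid=tp_map.grid, category=cat, area_fractions=pd.Series(fracs)
    )


def safe_boundary_report(metrics: dict[str, float]) -> dict[str, dict]:
    """Inside/on/outside status per water-stress driver.

    ``metrics`` maps driver names (see :data:`SAFE_BOUNDARIES`) to values;
    distance is signed in driver units, positive inside the safe space.
    """
    report = {}
    for name, value in metrics.items():
        if name not in SAFE_BOUNDARIES:
            raise KeyError(f"unknown safe-boundary driver {name!r}")
        boundary, safe_side = SAFE_BOUNDARIES[name]
        distance = (value - boundary) * safe_side
        status = "on_boundary" if distance == 0 else ("inside" if distance > 0 else "outside")
        report[name] = {
            "value": float(value),
            "boundary": boundary,
            "status": status,
            "distance": float(distance),
        }
    return report
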