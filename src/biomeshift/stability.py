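"""Ecosystem stability classes from annual rainfall and their 2050 projection.

Pixels are partitioned by mean annual precipitation against the two
critical rainfall thresholds: below the lower threshold only the
low-tree-cover state is stable (*stable savanna*), above the upper
threshold only the forest state (*stable forest*), and in between both
coexist (*bistable*). The classes double as index scores downstream:
0 for stable forest, 1 for bistable, 2 for stable savanna.

The 2050 projection evaluates each pixel's fitted rainfall regression line
at 2050 — only where the trend is significant (p < 0.1) — and reclassifies;
pixels without a significant trend keep their current class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateMetricMap, TrendMap, extrapolate_to_2050
from .grids import GridDescriptor, check_same_grid

__all__ = [
    "CLASS_FOREST",
    "CLASS_BISTABLE",
    "CLASS_SAVANNA",
    "CLASS_MASKED",
    "CLASS_NAMES",
    "StabilityClassMap",
    "classify_stability",
    "project_stability_2050",
    "transition_summary",
]

CLASS_FOREST = 0
CLASS_BISTABLE = 1
CLASS_SAVANNA = 2
CLASS_MASKED = -1
CLASS_NAMES = {CLASS_FOREST: "stable_forest", CLASS_BISTABLE: "bistable",
               CLASS_SAVANNA: "stable_savanna", CLASS_MASKED: "masked"}


@dataclass
class StabilityClassMap:
    """Per-pixel stability class (also the index score: 0/1/2; −1 masked)."""

    values: np.ndarray  # int8
    grid: GridDescriptor
    thresholds: tuple[float, float]
    epoch: str = "current"

    def fractions(self) -> pd.Series:
        """Class areal fractions over unmasked pixels."""
        valid = self.values[self.values != CLASS_MASKED]
        counts = pd.Series(valid.ravel()).value_counts(normalize=True)
        return counts.rename(index=CLASS_NAMES).sort_index()


def classify_stability(
    map_field: ClimateMetricMap, lower: float = 1000.0, upper: float = 1800.0
) -> StabilityClassMap:
    """Classify pixels by annual rainfall against the critical thresholds.

    Half-open bins with the wetter class winning at each boundary:
    MAP < lower → stable savanna; lower ≤ MAP < upper → bistable;
    MAP ≥ upper → stable forest. Non-finite rainfall → masked.
    """
    if lower >= upper:
        raise ValueError("lower threshold must be < upper threshold")
    m = map_field.values
    out = np.full(m.shape, CLASS_MASKED, dtype=np.int8)
    finite = np.isfinite(m)
    out[finite & (m < lower)] = CLASS_SAVANNA
    out[finite & (m >= lower) & (m < upper)] = CLASS_BISTABLE
    out[finite & (m >= upper)] = CLASS_FOREST
    return StabilityClassMap(out, map_field.grid, (lower, upper), epoch="current")


def transition_summary(
    current: StabilityClassMap, projected: StabilityClassMap
) -> pd.DataFrame:
    """Areal fraction of every current→projected class transition."""
    check_same_grid(current.grid, projected.grid)
    a, b = current.values.ravel(), projected.values.ravel()
    keep = (a != CLASS_MASKED) & (b != CLASS_MASKED)
    a, b = a[keep], b[keep]
    total = a.size
    rows = []
    for ca in (CLASS_FOREST, CLASS_BISTABLE, CLASS_SAVANNA):
        for cb in (CLASS_FOREST, CLASS_BISTABLE, CLASS_SAVANNA):
            frac = float(np.sum((a == ca) & (b == cb))) / total if total else np.nan
            rows.append(
                {"from": CLASS_NAMES[ca], "to": CLASS_NAMES[cb], "fraction": frac}
            )
    return pd.DataFrame(rows)


def project_stability_2050(
    map_now: ClimateMetricMap,
    rainfall_trend: TrendMap,
    lower: float = 1000.0,
    upper: float = 1800.0,
    target_year: int = 2050,
    slope_bound: float = 25.0,
) -> tuple[StabilityClassMap, pd.DataFrame]:
    """Project stability classes to 2050 using significant rainfall trends.

    Returns the projected class map and the current→2050 transition table.
    With no significant pixels (or zero slopes) the projection reproduces
    the current classes exactly.
    """
    check_same_grid(map_now.grid, rainfall_trend.grid)
    map_2050 = extrapolate_to_2050(
        rainfall_trend, map_now, target_year=target_year, slope_bound=slope_bound
    )
    current = classify_stability(map_now, lower, upper)
    projected = classify_stability(map_2050, lower, upper)
    projected.epoch = "2050"
    return projected, transition_summary(current, projected)
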