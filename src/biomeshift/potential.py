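"""Empirical potential analysis of tree cover along a climate axis.

The central idea: if high- and low-tree-cover ecosystems are alternative
stable states, the distribution of tree cover *conditional* on a climate
driver (annual rainfall, MCWD, dry-season length) is bimodal inside the
bistability range of that driver and unimodal outside it. Sliding a window
along the driver axis, estimating the probability density of tree cover in
each window, and reading its local maxima (stable equilibria) and the
minima between them (unstable equilibria) yields an empirical stability
landscape from purely cross-sectional data.

Density estimation uses a Gaussian kernel with Silverman's rule-of-thumb
bandwidth ``h = 1.06 σ n^(−1/5)``. Two filters suppress spurious modes:

* an absolute **density floor** (default 0.005) — maxima below it are
  ignored;
* a dimensionless **sensitivity** (default 0.005) — maxima whose
  topographic prominence falls below ``sensitivity × max(density)`` are
  treated as weak bumps, so raising the sensitivity strictly shrinks the
  retained-mode set.

Thresholds are read off the landscape: the *collapse threshold* is the
driest window at which the high-tree-cover state still exists, and the
*forest edge* is the wettest window at which the low state still exists;
between them lies the bistability range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KernelSpec",
    "ModeDetectionConfig",
    "WindowSpec",
    "WindowResult",
    "StabilityLandscape",
    "ThresholdResult",
    "silverman_bandwidth",
    "kde_density",
    "find_modes",
    "build_stability_landscape",
    "extract_thresholds",
    "sensitivity_sweep",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian KDE on a fixed tree-cover evaluation grid (0–100 %)."""

    grid_min: float = 0.0
    grid_max: float = 100.0
    grid_step: float = 0.5
    bandwidth_factor: float = 1.06  # Silverman prefactor

    def evaluation_grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + np.arange(n) * self.grid_step


@dataclass(frozen=True)
class ModeDetectionConfig:
    """Weak-mode filters: absolute density floor + relative prominence."""

    density_floor: float = 0.005
    sensitivity: float = 0.005

    def __post_init__(self) -> None:
        if self.density_floor <= 0 or self.sensitivity <= 0:
            raise ValueError("density_floor and sensitivity must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window layout along a climate driver axis.

    ``drier_is_high`` flips the orientation: for annual rainfall and MCWD
    drier means *lower* values, for dry-season length drier means *higher*.
    """

    variable: str
    step: float
    vrange: tuple[float, float]
    half_width: float
    drier_is_high: bool = False

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.half_width < self.step / 2:
            raise ValueError("half_width must be at least step/2")
        if self.vrange[0] >= self.vrange[1]:
            raise ValueError("range must be ordered")

    @classmethod
    def for_variable(cls, variable: str, half_width: float | None = None) -> "WindowSpec":
        presets = {
            "map": (10.0, (0.0, 3500.0), 50.0, False),
            "mcwd": (10.0, (-800.0, 0.0), 25.0, False),
            "dsl": (0.1, (0.0, 12.0), 0.5, True),
        }
        if variable not in presets:
            raise ValueError(f"unknown variable {variable!r}; use map|mcwd|dsl")
        step, vrange, hw, drier_high = presets[variable]
        return cls(variable, step, vrange, half_width if half_width is not None else hw,
                   drier_high)

    def centers(self) -> np.ndarray:
        lo, hi = self.vrange
        n = int(np.floor((hi - lo) / self.step + 1e-9)) + 1
        return lo + np.arange(n) * self.step


@dataclass
class WindowResult:
    """Equilibria found in one driver window."""

    center: float
    n_pixels: int
    usable: bool
    stable_positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    stable_densities: np.ndarray = field(default_factory=lambda: np.empty(0))
    unstable_positions: np.ndarray = field(default_factory=lambda: np.empty(0))

    def has_high(self, split: float) -> bool:
        return bool(np.any(self.stable_positions >= split))

    def has_low(self, split: float) -> bool:
        return bool(np.any(self.stable_positions < split))


@dataclass
class StabilityLandscape:
    """Stable/unstable tree-cover equilibria per driver window."""

    window: WindowSpec
    windows: list[WindowResult]
    split: float = 50.0  # tree cover (%) separating low from high states

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            rows.append(
                {
                    "center": w.center,
                    "n_pixels": w.n_pixels,
                    "usable": w.usable,
                    "n_stable": w.stable_positions.size,
                    "stable_positions": ";".join(f"{p:g}" for p in w.stable_positions),
                    "stable_densities": ";".join(f"{d:.6g}" for d in w.stable_densities),
                    "unstable_positions": ";".join(f"{p:g}" for p in w.unstable_positions),
                    "has_high": w.has_high(self.split),
                    "has_low": w.has_low(self.split),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ThresholdResult:
    """Critical thresholds read from a stability landscape.

    ``collapse_threshold`` — driest window centre at which the high state
    exists (beyond it, drier, only the low state remains).
    ``forest_edge`` — wettest window centre at which the low state exists
    (beyond it, wetter, only the high state remains).
    ``bistable_range`` — edges of the longest contiguous bimodal run, in
    ascending driver units (orientation-free).
    """

    variable: str
    collapse_threshold: float | None
    forest_edge: float | None
    bistable_range: tuple[float, float] | None
    fragmented: bool
    n_bimodal_windows: int

    # aliases on the raw driver axis (rainfall/MCWD naming)
    @property
    def lower_critical(self) -> float | None:
        return self.collapse_threshold

    @property
    def upper_critical(self) -> float | None:
        return self.forest_edge


def silverman_bandwidth(samples: np.ndarray, factor: float = 1.06) -> float:
    """Silverman's rule of thumb, ``h = 1.06 σ n^(−1/5)`` (sample sd)."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        raise ValueError("bandwidth needs at least 2 samples")
    sigma = samples.std(ddof=1)
    if sigma <= 0:
        raise ValueError("bandwidth undefined for zero-variance samples")
    return factor * sigma * n ** (-0.2)


def kde_density(
    samples: np.ndarray,
    spec: KernelSpec | None = None,
    n_min: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of tree cover on the evaluation grid.

    Returns ``(grid, density)``. Rejects windows with fewer than ``n_min``
    samples or zero variance (degenerate landscape windows are flagged by
    the caller rather than silently smoothed).
    """
    spec = spec or KernelSpec()
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < n_min:
        raise ValueError(f"window has {samples.size} samples; need >= {n_min}")
    h = silverman_bandwidth(samples, spec.bandwidth_factor)
    grid = spec.evaluation_grid()
    # chunk over samples to bound memory on big windows
    density = np.zeros_like(grid)
    for start in range(0, samples.size, 20000):
        chunk = samples[start : start + 20000]
        z = (grid[:, None] - chunk[None, :]) / h
        density += np.exp(-0.5 * z * z).sum(axis=1)
    density /= samples.size * h * np.sqrt(2.0 * np.pi)
    return grid, density


def _plateau_maxima(density: np.ndarray) -> list[int]:
    """Indices of local maxima, plateau-aware (leftmost point of a plateau).

    Boundary maxima are retained: tree cover is physically bounded at 0 and
    100 %, so a mode pressed against a bound is still a mode.
    """
    # run-length encode consecutive equal values
    d = np.asarray(density, dtype=float)
    change = np.nonzero(np.diff(d))[0] + 1
    starts = np.concatenate(([0], change))
    vals = d[starts]
    peaks = []
    for k, s in enumerate(starts):
        left_ok = k == 0 or vals[k - 1] < vals[k]
        right_ok = k == len(starts) - 1 or vals[k + 1] < vals[k]
        if left_ok and right_ok:
            peaks.append(int(s))
    return peaks


def _prominence(density: np.ndarray, peak: int) -> float:
    """Topographic prominence of ``density[peak]``.

    Walk outward on each side until terrain higher than the peak is found;
    the saddle is the higher of the two side minima. A global maximum's
    prominence is its own height.
    """
    h = density[peak]
    saddles = []
    for step in (-1, 1):
        i = peak
        side_min = h
        found_higher = False
        while 0 <= i + step < density.size:
            i += step
            if density[i] > h:
                found_higher = True
                break
            side_min = min(side_min, density[i])
        if found_higher:
            saddles.append(side_min)
    if not saddles:
        return float(h)
    return float(h - max(saddles))


def find_modes(
    grid: np.ndarray,
    density: np.ndarray,
    cfg: ModeDetectionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stable and unstable equilibria of a tree-cover density.

    Returns ``(stable_positions, stable_densities, unstable_positions)``.
    Stable equilibria are local maxima passing both the density floor and
    the relative-prominence sensitivity filter; the unstable equilibrium
    between two consecutive retained maxima is the deepest minimum between
    them (leftmost grid point on a plateau).
    """
    cfg = cfg or ModeDetectionConfig()
    density = np.asarray(density, dtype=float)
    if density.size == 0:
        raise ValueError("empty density")
    global_max = density.max()
    candidates = _plateau_maxima(density)
    kept = [
        i
        for i in candidates
        if density[i] >= cfg.density_floor
        and _prominence(density, i) >= cfg.sensitivity * global_max
    ]
    kept.sort()
    stable_pos = np.asarray([grid[i] for i in kept])
    stable_den = np.asarray([density[i] for i in kept])
    unstable = []
    for a, b in zip(kept[:-1], kept[1:]):
        seg = density[a : b + 1]
        unstable.append(grid[a + int(np.argmin(seg))])
    return stable_pos, stable_den, np.asarray(unstable)


def _window_samples(
    tree_cover: np.ndarray,
    metric_values: np.ndarray,
    exclusion_mask: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    tc = np.asarray(tree_cover, dtype=float).ravel()
    mv = np.asarray(metric_values, dtype=float).ravel()
    if tc.shape != mv.shape:
        raise ValueError("tree cover and climate metric must share a grid")
    keep = np.isfinite(tc) & np.isfinite(mv)
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool).ravel()
    return tc[keep], mv[keep]


def build_stability_landscape(
    tree_cover: np.ndarray,
    metric_values: np.ndarray,
    window: WindowSpec,
    kernel: KernelSpec | None = None,
    modes: ModeDetectionConfig | None = None,
    exclusion_mask: np.ndarray | None = None,
    n_min: int = 100,
    split: float = 50.0,
) -> StabilityLandscape:
    """Sliding-window potential analysis of tree cover along a driver axis.

    Pixels under ``exclusion_mask`` (e.g. deforested by 2020) are dropped
    before windowing. Windows with fewer than ``n_min`` pixels or zero
    tree-cover variance are flagged unusable.
    """
    kernel = kernel or KernelSpec()
    modes = modes or ModeDetectionConfig()
    tc, mv = _window_samples(tree_cover, metric_values, exclusion_mask)
    order = np.argsort(mv, kind="stable")
    mv_sorted = mv[order]
    tc_sorted = tc[order]
    results: list[WindowResult] = []
    for c in window.centers():
        lo = np.searchsorted(mv_sorted, c - window.half_width, side="left")
        hi = np.searchsorted(mv_sorted, c + window.half_width, side="right")
        sample = tc_sorted[lo:hi]
        n = sample.size
        if n < n_min or (n >= 2 and sample.std(ddof=1) == 0):
            results.append(WindowResult(center=float(c), n_pixels=int(n), usable=False))
            continue
        grid, density = kde_density(sample, kernel, n_min=n_min)
        sp, sd, up = find_modes(grid, density, modes)
        results.append(
            WindowResult(
                center=float(c),
                n_pixels=int(n),
                usable=True,
                stable_positions=sp,
                stable_densities=sd,
                unstable_positions=up,
            )
        )
    if not any(w.usable for w in results):
        raise ValueError("no usable windows: too few pixels everywhere on the axis")
    return StabilityLandscape(window=window, windows=results, split=split)


def extract_thresholds(landscape: StabilityLandscape) -> ThresholdResult:
    """Critical thresholds and bistability range from a landscape.

    Orientation-aware: for MCWD and annual rainfall "drier" is the low end
    of the axis, for DSL the high end; the collapse threshold is always
    reported on the drier side. If bimodal windows are fragmented into
    several runs, the longest run is used and the result flagged.
    """
    usable = [w for w in landscape.windows if w.usable]
    split = landscape.split
    centers = np.asarray([w.center for w in usable])
    has_high = np.asarray([w.has_high(split) for w in usable])
    has_low = np.asarray([w.has_low(split) for w in usable])
    bimodal = has_high & has_low

    variable = landscape.window.variable
    n_bimodal = int(bimodal.sum())
    if n_bimodal == 0:
        return ThresholdResult(variable, None, None, None, False, 0)

    # longest contiguous run of bimodal windows (indices in usable order)
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(bimodal):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(bimodal) - 1))
    longest = max(runs, key=lambda r: r[1] - r[0])
    run_lo, run_hi = centers[longest[0]], centers[longest[1]]

    drier_high = landscape.window.drier_is_high
    if drier_high:
        # drier = larger axis values (DSL)
        collapse = float(centers[has_high].max()) if has_high.any() else None
        forest_edge = float(centers[has_low].min()) if has_low.any() else None
    else:
        collapse = float(centers[has_high].min()) if has_high.any() else None
        forest_edge = float(centers[has_low].max()) if has_low.any() else None
    bistable = (float(run_lo), float(run_hi))
    return ThresholdResult(
        variable=variable,
        collapse_threshold=collapse,
        forest_edge=forest_edge,
        bistable_range=bistable,
        fragmented=len(runs) > 1,
        n_bimodal_windows=n_bimodal,
    )


def sensitivity_sweep(
    tree_cover: np.ndarray,
    metric_values: np.ndarray,
    window: WindowSpec,
    sensitivity_values: list[float],
    kernel: KernelSpec | None = None,
    density_floor: float = 0.005,
    exclusion_mask: np.ndarray | None = None,
    n_min: int = 100,
    split: float = 50.0,
) -> pd.DataFrame:
    """Thresholds as a function of the weak-mode sensitivity parameter.

    Densities are estimated once per window; only mode detection is re-run
    per sensitivity value, so the sweep scales with the number of values.
    Retained-mode counts are non-increasing in the sensitivity.
    """
    if len(sensitivity_values) < 2:
        raise ValueError("sweep needs at least 2 sensitivity values")
    kernel = kernel or KernelSpec()
    tc, mv = _window_samples(tree_cover, metric_values, exclusion_mask)
    order = np.argsort(mv, kind="stable")
    mv_sorted, tc_sorted = mv[order], tc[order]
    densities: list[tuple[float, int, np.ndarray, np.ndarray] | None] = []
    for c in window.centers():
        lo = np.searchsorted(mv_sorted, c - window.half_width, side="left")
        hi = np.searchsorted(mv_sorted, c + window.half_width, side="right")
        sample = tc_sorted[lo:hi]
        if sample.size < n_min or (sample.size >= 2 and sample.std(ddof=1) == 0):
            densities.append((float(c), int(sample.size), None, None))
            continue
        grid, dens = kde_density(sample, kernel, n_min=n_min)
        densities.append((float(c), int(sample.size), grid, dens))

    rows = []
    for s in sensitivity_values:
        cfg = ModeDetectionConfig(density_floor=density_floor, sensitivity=s)
        windows = []
        total_modes = 0
        for c, n, grid, dens in densities:
            if grid is None:
                windows.append(WindowResult(center=c, n_pixels=n, usable=False))
                continue
            sp, sd, up = find_modes(grid, dens, cfg)
            total_modes += sp.size
            windows.append(
                WindowResult(c, n, True, sp, sd, up)
            )
        landscape = StabilityLandscape(window=window, windows=windows, split=split)
        thr = extract_thresholds(landscape)
        rows.append(
            {
                "sensitivity": s,
                "total_modes": total_modes,
                "collapse_threshold": thr.collapse_threshold,
                "forest_edge": thr.forest_edge,
                "bistable_lo": thr.bistable_range[0] if thr.bistable_range else np.nan,
                "bistable_hi": thr.bistable_range[1] if thr.bistable_range else np.nan,
                "n_bimodal_windows": thr.n_bimodal_windows,
            }
        )
    return pd.DataFrame(rows)
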