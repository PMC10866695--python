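# Methods

## Scientific problem

Tropical tree cover in South America does not respond smoothly to water
availability. Over a broad band of climatic conditions, high-tree-cover
forest and low-tree-cover savanna both persist as alternative stable
states: which one a location occupies depends on its disturbance history,
and a severe disturbance can tip a forest into the open state with little
prospect of spontaneous recovery. `biomeshift` implements the analytical
chain used to detect this bistability from cross-sectional data, to map
where compounding disturbances make a transition most likely by 2050, and
to quantify the atmospheric moisture recycling that couples forest loss in
one region to rainfall decline downwind. Everything runs on synthetic data
with known ground truth, so every stage is testable end to end without
external downloads.

## Empirical potential analysis

The core statistic is the conditional distribution of tree cover *T* (%)
given a climate driver *c* (annual rainfall, maximum cumulative water
deficit, or dry-season length). If the system is bistable inside a driver
range, the conditional density p(T | c) is bimodal there and unimodal
outside. The procedure:

1. **Windowing.** Pixels are pooled into moving windows along the driver
   axis: 10 mm yr⁻¹ steps over 0–3500 mm yr⁻¹ for annual rainfall, 10 mm
   steps over −800–0 mm for MCWD, 0.1-month steps over 0–12 months for
   DSL. The window half-width is not part of the published recipe; we use
   50 mm (rainfall), 25 mm (MCWD) and 0.5 month (DSL) — at least five axis
   steps, enough sample depth per window without blurring the thresholds.
   Windows with fewer than `n_min` = 100 pixels, or with zero tree-cover
   variance, are flagged unusable. Deforested pixels are excluded before
   windowing.
2. **Density estimation.** Gaussian-kernel density on a fixed 0–100 %
   evaluation grid (0.5 % step) with Silverman's rule-of-thumb bandwidth
   h = 1.06 σ n^(−1/5) (sample standard deviation σ, window sample size
   n). The negative exponent is the standard rule; a bandwidth *growing*
   with n is not meaningful.
3. **Mode detection.** Interior and boundary local maxima of the density
   are candidate stable equilibria (tree cover is physically bounded, so a
   mode pressed against 0 or 100 % is retained; plateau maxima resolve to
   their leftmost grid point). Two filters remove spurious modes: an
   absolute density floor of 0.005, and a dimensionless sensitivity of
   0.005 interpreted as *relative topographic prominence* — a maximum is
   kept only if its prominence is at least `sensitivity × max(density)`.
   The prominence reading makes the filter dimensionless and guarantees
   that raising the sensitivity never increases the retained-mode count,
   which is the behaviour the sensitivity sweep relies on. The deepest
   minimum between two consecutive retained maxima is the unstable
   equilibrium, so stable and unstable equilibria alternate by
   construction.
4. **Threshold extraction.** A window is bimodal when it has a retained
   mode on each side of the 50 % tree-cover split. The *collapse
   threshold* is the driest window at which the high-cover state still
   exists; the *forest edge* is the wettest window at which the low-cover
   state still exists; the bistability range is the longest contiguous
   bimodal run (fragmentation is flagged). Orientation is handled per
   driver: drier means lower values for rainfall and MCWD, higher values
   for DSL.

Ground truths for recovery: rainfall 1000/1800 mm yr⁻¹, MCWD −450/−350 mm,
DSL 5/8 months.

### Expected recovery bias

Detection of a mode requires its KDE peak to clear the 0.005 floor, which
happens once the minority component carries roughly 10 % of a window's
pixels. With a uniform driver distribution inside a window of half-width
w, the forest mode therefore becomes detectable about 0.2–0.6 w *before*
the window centre crosses the true threshold. At the default widths this
is a ≲ 30 mm (rainfall), ≲ 15 mm (MCWD), ≲ 0.3 month (DSL) outward bias —
well inside the stated recovery tolerances, and the reason recovered
ranges are a shade wider than the truth rather than narrower.

## Climate metrics

* **MAP** — mean over years of the annual precipitation sums (mm yr⁻¹).
* **MCWD** — within each year the running deficit WDₙ = min(0, WDₙ₋₁ + Pₙ −
  E) with WD₀ = 0; the year's MCWD is the most negative month. The
  reference evapotranspiration E is fixed at 100 mm month⁻¹, the
  convention of the tropical-forest drought literature; it is a parameter,
  and an actual-evapotranspiration field can be passed instead by changing
  `evap_ref`. The climatological MCWD is the mean of the annual values.
* **DSL** — count of climatological months strictly below 100 mm (the
  conventional tropical dry-month criterion; configurable). The count is
  monotonically non-increasing in the threshold's complement by
  construction.
* **Dry-season temperature** — per-year July–October mean.

**Trend screening.** Per-pixel ordinary least squares of a yearly series
against calendar year, vectorised over the grid; two-sided p-value from
the slope's t statistic; significance at α = 0.1 with no multiple-testing
correction (the screening is per-pixel by design). Degenerate cases:
fewer than 3 finite years → masked; zero response variance → slope 0,
p undefined, not significant; a perfect noise-free fit → p numerically 0,
significant.

**2050 projection.** Where a rainfall trend is significant, the fitted
line is evaluated at year 2050 (deterministic, noise-free), otherwise the
present value is kept; classes are then re-derived. A sanity guard rejects
|slope| > 25 mm yr⁻¹ yr⁻¹ as physically implausible (observed extremes are
near ±20).

**Extreme droughts.** Years whose annual MCWD is at least 2 standard
deviations below the reference mean, counted within the 2001–2018 window
and capped at 5 events. The published "historical mean" baseline is
ambiguous; by default the reference mean/sd come from the analysed window
itself, and both can be supplied explicitly to use a longer baseline.

## Stability classes and the transition-potential index

Annual rainfall against the two critical thresholds partitions pixels into
stable savanna (< lower), bistable (between) and stable forest (≥ upper);
bins are half-open with the wetter class winning on the boundary, a
convention that is immaterial at 10-mm window resolution. Only the
rainfall axis drives classification; the MCWD and DSL landscapes are
reported alongside but not fused, since no fusion rule is published.

The transition-potential index is a plain sum of five layers: 10 × the
significant dry-season warming slope (°C yr⁻¹), the 2050 class score
(0/1/2), 0.2 per extreme-drought event, +1 within 10 km of a road, −1
inside protected areas or Indigenous territories. Deforested and
savanna-biome pixels are excluded. With zero temperature trend the index
spans exactly −1 to 4; with observed slopes in [−0.01, 0.06] °C yr⁻¹ the
theoretical envelope is [−1.1, 4.6]. Road proximity uses exact
great-circle point-to-geodesic-segment distances (the grid is geographic
and 10 km is small against the Earth radius, but planar error is material
right at the boundary).

Categories: the figure legend ("< 0 low, 1–2 moderate, > 2 high") leaves
[0, 1) unlabelled, while the running text counts "more than 1" and "more
than 2" disturbance types cumulatively. The default rule therefore breaks
at 1 and 2 (low ≤ 1 < moderate ≤ 2 < high); the figure's rule is available
as `category_rule="figure"`.

Safe boundaries are fixed reference constants per driver — 1800 mm yr⁻¹
annual rainfall, −350 mm MCWD, 5 months DSL, 10 % accumulated
deforestation — reported as inside / on-boundary / outside with a signed
distance in driver units.

## Moisture tracking

A simplified forward Lagrangian tracker: each cell releases
round(E × 100) parcels per mm of evapotranspiration, splitting the cell's
evaporation equally; positions update every 0.1 h with bilinearly
interpolated single-layer wind, metres converted to degrees at the
parcel's latitude; at each step a parcel sheds the fraction
min(1, P·dt/TPW) of its remaining moisture to the cell below (the
well-mixed allocation rule); parcels terminate below 1 % of their released
moisture, beyond a 30-day horizon, or on leaving the domain (booked as
exited). The ledger is a dense source-cell × target-cell matrix, so
released = allocated + exited + residual holds to floating-point rounding
on every run, and region-to-region flow matrices follow by summation.
Rainfall fractions are computed on the *tracked subset*: only domain
evaporation is tracked, so a target's fraction understates its true
recycled share. The published 25-layer vertical structure and the
vertical shuffling of the source model are deliberately out of scope —
with steady single-layer forcing the tracker has a closed-form limit
(downwind allocation ∝ exp(−x/L), L = u·TPW/P) that the tests exploit.

## Synthetic data: what it emulates, and what it does not

* **Tree cover** is drawn per pixel from the savanna mode N(20, 10²)
  below/drier than the lower threshold, the forest mode N(85, 8²)
  above/wetter than the upper, and a 0.5/0.5 mixture in between, clipped
  to [0, 100]. A mixture — not a mechanistic hysteresis model — because
  cross-sectional data cannot distinguish the two and the potential
  analysis needs only conditional bimodality. Mode positions and sds keep
  the modes separable under the 0.005 floor at a few thousand pixels per
  window. The driver field is a west–east gradient spanning the axis
  range with sub-column uniform jitter. For the DSL axis the generated
  driver is continuous in [0, 12] months even though the DSL *metric* of
  an observed cube is integer-valued: the landscape needs a continuous
  conditioning variable to resolve 0.1-month windows.
* **Climate cubes** are climatology + year-indexed linear trend +
  Gaussian noise truncated at zero for precipitation (the simplest model
  satisfying non-negativity). Defaults: a 2000 mm yr⁻¹ seasonal monthly
  profile, 0.027 °C yr⁻¹ injected warming (the observed 0.27 °C/decade
  dry-season rate), monthly noise of 15 mm and 0.15 °C — magnitudes of
  the right order for interannual tropical variability, chosen once.
  Injected slopes are returned as ground truth.
* **Disturbances**: drought counts are Binomial(5, λ/5) (integer support
  0–5, mean λ, default 1.5); roads are random-walk polylines (only
  distance-to-road matters downstream); protection and deforestation
  masks are quantile-thresholded smoothed noise fields, mutually
  exclusive, hitting target fractions (defaults 30 % and 15 %) almost
  exactly.
* **Not emulated**: sensor error structure of satellite tree cover,
  river/floodplain geomorphology, spatial autocorrelation of climate
  noise, scenario-style future forcing. Passing recovery tests therefore
  demonstrates that the *method* inverts the data-generating process it
  assumes — not that satellite tree-cover products are free of artefacts
  that could masquerade as bimodality.

## Numerical choices and degenerate inputs

Evaluation grid 0.5 % tree cover; KDE chunked over samples to bound
memory; thresholds reported at window-centre resolution (one step
granularity). Tie-breaks: plateau maxima → leftmost point; fragmented
bimodal runs → longest run, flagged. Zero-variance or undersized windows
are flagged, never smoothed over. The trend fit guards against zero
time-variance, zero response-variance and perfect fits separately. The
drought detector returns 0 events when the reference sd is 0. All
generators are bit-reproducible under a fixed seed, and the pipeline
report is byte-identical across runs with the same seed.

## Problem sizes

Recovery studies use the default 10⁵-pixel biome (250 × 400) and 20 seeds
for the headline medians; unit tests use a 16k-pixel biome, which already
recovers thresholds within the stated tolerances. The moisture
conservation/decay study uses a 50 × 50 grid with 20,000 parcels; the
pipeline demonstration uses 120 × 200 pixels. These sizes resolve every
quantity the package asserts while keeping a full run in minutes on one
CPU.

## Known limitations

* The potential analysis detects *conditional bimodality*, which is
  consistent with — but not proof of — alternative stable states;
  unresolved environmental heterogeneity can mimic it.
* The detection bias described above means recovered bistability ranges
  are systematically a few window-widths wider than the truth; the effect
  shrinks with the density floor and window width.
* The index is additive by design and ignores synergies between
  disturbances; it is a relative ranking, not a probability.
* The tracker is single-layer and forward-only; its fractions are shares
  of tracked moisture, not of total observed rainfall.
* I/O uses ESRI ASCII grids and NetCDF3; pixel-centre geographic grids
  only, with a nearest-neighbour regridder (warning attached) for
  pre-harmonising mixed-resolution inputs.
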