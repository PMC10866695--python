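"""Potential analysis: KDE oracle, mode detection, threshold extraction."""

import numpy as np
import pytest
from scipy import optimize, stats

import biomeshift as bs
from biomeshift.potential import _plateau_maxima, _prominence


class TestKde:
    def test_matches_brute_force_gaussian_sum(self, rng):
        """Pointwise equality with an explicit double-loop Gaussian sum."""
        samples = rng.uniform(0, 100, 500)
        grid, density = bs.kde_density(samples)
        h = bs.silverman_bandwidth(samples)
        ref = np.zeros_like(grid)
        for k, g in enumerate(grid):
            acc = 0.0
            for x in samples:
                acc += np.exp(-0.5 * ((g - x) / h) ** 2)
            ref[k] = acc / (len(samples) * h * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(density, ref, rtol=0, atol=1e-12)

    def test_symmetric_samples_symmetric_density(self):
        samples = np.concatenate([50 - np.linspace(1, 30, 200), 50 + np.linspace(1, 30, 200)])
        _, density = bs.kde_density(samples)
        np.testing.assert_allclose(density, density[::-1], atol=1e-10)

    def test_small_windows_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            bs.kde_density(np.array([50.0]), n_min=100)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            bs.kde_density(np.full(200, 42.0))

    def test_near_unit_integral(self, rng):
        samples = rng.normal(50, 10, 2000)
        grid, density = bs.kde_density(samples)
        integral = np.trapezoid(density, grid)
        assert abs(integral - 1.0) < 1e-3

    def test_silverman_rule_value(self):
        x = np.arange(100, dtype=float)
        h = bs.silverman_bandwidth(x)
        assert h == pytest.approx(1.06 * x.std(ddof=1) * 100 ** (-0.2))


def mixture_density(grid, w, m1, s1, m2, s2):
    return w * stats.norm.pdf(grid, m1, s1) + (1 - w) * stats.norm.pdf(grid, m2, s2)


class TestFindModes:
    def test_single_gaussian_one_stable_no_unstable(self):
        grid = np.arange(0, 100.5, 0.5)
        density = stats.norm.pdf(grid, 50, 8)
        sp, sd, up = bs.find_modes(grid, density)
        assert sp.size == 1 and up.size == 0
        assert sp[0] == pytest.approx(50, abs=0.5)

    def test_two_gaussian_mixture_matches_analytic_roots(self):
        """Mode/antimode positions agree with the mixture derivative's roots
        (independent oracle: brentq on the analytic derivative)."""
        grid = np.arange(0, 100.5, 0.5)
        params = (0.45, 20.0, 10.0, 85.0, 8.0)
        density = mixture_density(grid, *params)
        sp, sd, up = bs.find_modes(grid, density)
        assert sp.size == 2 and up.size == 1

        def ddx(x):
            w, m1, s1, m2, s2 = params
            return -w * (x - m1) / s1**2 * stats.norm.pdf(x, m1, s1) - (1 - w) * (
                x - m2
            ) / s2**2 * stats.norm.pdf(x, m2, s2)

        root_lo = optimize.brentq(ddx, 10, 30)
        root_hi = optimize.brentq(ddx, 75, 95)
        root_mid = optimize.brentq(ddx, 40, 70)
        assert sp[0] == pytest.approx(root_lo, abs=0.5)
        assert sp[1] == pytest.approx(root_hi, abs=0.5)
        assert up[0] == pytest.approx(root_mid, abs=0.5)

    def test_floor_filters_everything(self):
        grid = np.arange(0, 100.5, 0.5)
        density = 0.001 * stats.norm.pdf(grid, 50, 8) / stats.norm.pdf(50, 50, 8)
        sp, _, up = bs.find_modes(grid, density)
        assert sp.size == 0 and up.size == 0

    def test_plateau_tiebreak_leftmost(self):
        density = np.array([0.0, 0.1, 0.3, 0.3, 0.3, 0.1, 0.0])
        peaks = _plateau_maxima(density)
        assert peaks == [2]

    def test_boundary_maxima_retained(self):
        grid = np.arange(0, 100.5, 0.5)
        density = stats.norm.pdf(grid, 0, 5) * 2  # mode pressed against 0
        sp, _, _ = bs.find_modes(grid, density)
        assert sp.size >= 1 and sp[0] == 0.0

    def test_prominence_of_global_max_is_height(self):
        density = np.array([0.0, 0.5, 0.2, 0.4, 0.1])
        assert _prominence(density, 1) == pytest.approx(0.5)
        assert _prominence(density, 3) == pytest.approx(0.2)

    def test_empty_density_rejected(self):
        with pytest.raises(ValueError):
            bs.find_modes(np.array([]), np.array([]))


class TestLandscape:
    def test_all_wet_pixels_every_window_forest(self):
        cfg = bs.SyntheticBiomeConfig(grid_shape=(60, 60), seed=4)
        axis = np.full((60, 60), 2500.0)
        tc = bs.generate_tree_cover(cfg, axis)
        window = bs.WindowSpec.for_variable("map")
        ls = bs.build_stability_landscape(tc, axis, window)
        for w in ls.windows:
            if w.usable:
                assert w.has_high(ls.split) and not w.has_low(ls.split)

    def test_bistable_band_windows_report_two_states(self, biome_small):
        cfg, axis, tc = biome_small
        ls = bs.build_stability_landscape(tc, axis, bs.WindowSpec.for_variable("map"))
        mid = [w for w in ls.windows if w.usable and 1300 <= w.center <= 1500]
        assert mid and all(w.stable_positions.size == 2 for w in mid)

    def test_masking_bistable_pixels_removes_bimodality(self, biome_small):
        cfg, axis, tc = biome_small
        exclusion = (axis > cfg.true_lower_threshold) & (axis < cfg.true_upper_threshold)
        ls = bs.build_stability_landscape(
            tc, axis, bs.WindowSpec.for_variable("map"), exclusion_mask=exclusion
        )
        thr = bs.extract_thresholds(ls)
        assert thr.n_bimodal_windows == 0 and thr.bistable_range is None

    def test_stable_unstable_alternation(self, biome_small):
        """Between any two consecutive stable equilibria lies exactly one
        unstable one, strictly ordered along the tree-cover axis."""
        cfg, axis, tc = biome_small
        ls = bs.build_stability_landscape(tc, axis, bs.WindowSpec.for_variable("map"))
        for w in ls.windows:
            if not w.usable:
                continue
            assert w.unstable_positions.size == max(w.stable_positions.size - 1, 0)
            merged = np.empty(w.stable_positions.size + w.unstable_positions.size)
            merged[0::2] = w.stable_positions
            merged[1::2] = w.unstable_positions
            assert np.all(np.diff(merged) > 0)

    def test_no_usable_windows_is_an_error(self):
        window = bs.WindowSpec.for_variable("map")
        with pytest.raises(ValueError, match="usable"):
            bs.build_stability_landscape(
                np.random.default_rng(0).uniform(0, 100, 50),
                np.full(50, 1500.0),
                window,
                n_min=100,
            )

    def test_threshold_recovery_small_biome(self, biome_small):
        cfg, axis, tc = biome_small
        ls = bs.build_stability_landscape(tc, axis, bs.WindowSpec.for_variable("map"))
        thr = bs.extract_thresholds(ls)
        assert thr.collapse_threshold == pytest.approx(cfg.true_lower_threshold, abs=50)
        assert thr.forest_edge == pytest.approx(cfg.true_upper_threshold, abs=50)

    def test_unimodal_landscape_no_thresholds(self):
        cfg = bs.SyntheticBiomeConfig(grid_shape=(60, 60), seed=4)
        axis = np.full((60, 60), 2500.0)
        tc = bs.generate_tree_cover(cfg, axis)
        ls = bs.build_stability_landscape(tc, axis, bs.WindowSpec.for_variable("map"))
        thr = bs.extract_thresholds(ls)
        assert thr.bistable_range is None and thr.n_bimodal_windows == 0

    def test_dsl_orientation_collapse_on_dry_side(self):
        cfg = bs.SyntheticBiomeConfig.for_axis("dsl", grid_shape=(100, 160), seed=21)
        axis = bs.generate_axis_field(cfg)
        tc = bs.generate_tree_cover(cfg, axis)
        ls = bs.build_stability_landscape(tc, axis, bs.WindowSpec.for_variable("dsl"))
        thr = bs.extract_thresholds(ls)
        # collapse threshold is on the dry (long dry season) side
        assert thr.collapse_threshold > thr.forest_edge
        assert thr.collapse_threshold == pytest.approx(8.0, abs=0.5)
        assert thr.forest_edge == pytest.approx(5.0, abs=0.5)


class TestSensitivitySweep:
    def test_mode_counts_monotone_in_sensitivity(self, biome_small):
        cfg, axis, tc = biome_small
        table = bs.sensitivity_sweep(
            tc, axis, bs.WindowSpec.for_variable("map"), [0.001, 0.005, 0.01, 0.1, 0.9]
        )
        counts = table["total_modes"].to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_large_sensitivity_leaves_unimodal_windows(self, biome_small):
        cfg, axis, tc = biome_small
        table = bs.sensitivity_sweep(
            tc, axis, bs.WindowSpec.for_variable("map"), [0.005, 2.0]
        )
        assert table.iloc[-1]["n_bimodal_windows"] == 0

    def test_threshold_spread_small_across_default_sweep(self, biome_small):
        cfg, axis, tc = biome_small
        window = bs.WindowSpec.for_variable("map")
        table = bs.sensitivity_sweep(tc, axis, window, [0.001, 0.005, 0.01])
        spread = table["collapse_threshold"].max() - table["collapse_threshold"].min()
        assert spread <= 2 * window.half_width

    def test_needs_two_values(self, biome_small):
        cfg, axis, tc = biome_small
        with pytest.raises(ValueError):
            bs.sensitivity_sweep(tc, axis, bs.WindowSpec.for_variable("map"), [0.005])
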