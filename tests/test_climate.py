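"""Climate metrics against brute-force oracles and worked examples."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import biomeshift as bs
from conftest import make_cube


def uniform_cube(monthly_value, grid, n_years=5, start=2000):
    values = np.full((n_years, 12) + grid.shape, float(monthly_value))
    return make_cube(values, np.arange(start, start + n_years), grid)


class TestMap:
    def test_uniform_100mm_gives_1200(self, small_grid):
        m = bs.compute_map(uniform_cube(100.0, small_grid))
        np.testing.assert_allclose(m.values, 1200.0)

    def test_all_zero_precipitation(self, small_grid):
        m = bs.compute_map(uniform_cube(0.0, small_grid))
        np.testing.assert_allclose(m.values, 0.0)

    def test_random_cube_matches_loop_oracle(self, small_grid, rng):
        values = rng.uniform(0, 300, (6, 12) + small_grid.shape)
        cube = make_cube(values, np.arange(2000, 2006), small_grid)
        result = bs.compute_map(cube).values
        # brute-force: explicit loops over years and months
        for i in range(0, small_grid.rows, 7):
            for j in range(0, small_grid.cols, 11):
                totals = [sum(values[y, m, i, j] for m in range(12)) for y in range(6)]
                assert abs(result[i, j] - sum(totals) / 6) < 1e-12 * max(totals)


class TestMcwd:
    def test_uniform_100_with_e100_is_zero(self, small_grid):
        m = bs.compute_mcwd(uniform_cube(100.0, small_grid))
        np.testing.assert_allclose(m.values, 0.0)

    def test_zero_precip_full_year_deficit(self, small_grid):
        m = bs.compute_mcwd(uniform_cube(0.0, small_grid))
        np.testing.assert_allclose(m.values, -1200.0)

    def test_negative_evap_rejected(self, small_grid):
        with pytest.raises(ValueError):
            bs.compute_mcwd(uniform_cube(100.0, small_grid), evap_ref=-5.0)

    @given(
        monthly=st.lists(st.floats(0, 400, allow_nan=False), min_size=12, max_size=12)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_seasonal_series_matches_recurrence_oracle(self, monthly):
        grid = bs.GridDescriptor(rows=1, cols=1)
        values = np.asarray(monthly)[None, :, None, None]
        cube = make_cube(values, [2000], grid)
        got = bs.compute_mcwd(cube).values[0, 0]
        wd, worst = 0.0, 0.0
        for p in monthly:
            wd = min(0.0, wd + p - 100.0)
            worst = min(worst, wd)
        assert got == pytest.approx(worst, abs=1e-9)
        assert got <= 0


class TestDsl:
    def test_all_wet_months_zero(self, small_grid):
        m = bs.compute_dsl(uniform_cube(150.0, small_grid))
        np.testing.assert_array_equal(m.values, 0)

    def test_boundary_month_is_strict(self, small_grid):
        values = np.full((3, 12) + small_grid.shape, 150.0)
        values[:, 4] = 100.0  # exactly at the threshold: not dry
        cube = make_cube(values, [2000, 2001, 2002], small_grid)
        np.testing.assert_array_equal(bs.compute_dsl(cube).values, 0)

    def test_worked_climatology_counts_seven(self):
        grid = bs.GridDescriptor(rows=1, cols=1)
        monthly = [120, 110, 95, 80, 60, 40, 30, 50, 90, 130, 140, 160]
        values = np.asarray(monthly, float)[None, :, None, None]
        cube = make_cube(values, [2000], grid)
        assert bs.compute_dsl(cube).values[0, 0] == 7

    def test_monotone_in_threshold(self, small_grid, rng):
        values = rng.uniform(0, 250, (4, 12) + small_grid.shape)
        cube = make_cube(values, np.arange(2000, 2004), small_grid)
        previous = None
        for thr in (50, 100, 150, 200):
            dsl = bs.compute_dsl(cube, dry_month_threshold=thr).values
            if previous is not None:
                assert np.all(dsl >= previous)
            previous = dsl


class TestDrySeasonTemperature:
    def test_constant_series(self, small_grid):
        series = bs.dry_season_temperature(uniform_cube(25.0, small_grid))
        np.testing.assert_allclose(series, 25.0)

    def test_july_to_october_mean(self, small_grid):
        values = np.zeros((1, 12) + small_grid.shape)
        values[0, 6], values[0, 7], values[0, 8], values[0, 9] = 26, 27, 28, 29
        cube = make_cube(values, [2000], small_grid)
        np.testing.assert_allclose(bs.dry_season_temperature(cube)[0], 27.5)

    def test_random_cube_matches_mean_oracle(self, small_grid, rng):
        values = rng.uniform(20, 35, (5, 12) + small_grid.shape)
        cube = make_cube(values, np.arange(2000, 2005), small_grid)
        got = bs.dry_season_temperature(cube)
        np.testing.assert_allclose(got, values[:, 6:10].mean(axis=1), atol=1e-12)


class TestFitTrend:
    def test_perfect_linear_trend(self):
        years = np.arange(1981, 2021)
        y = 0.03 * (years - 1981) + 20.0
        trend = bs.fit_trend(y, years)
        assert trend.slope[0, 0] == pytest.approx(0.03, abs=1e-10)
        assert trend.p_value[0, 0] < 1e-50  # numerically zero for a perfect fit
        assert trend.significant[0, 0]

    def test_constant_series_not_significant(self):
        years = np.arange(2000, 2010)
        trend = bs.fit_trend(np.full(10, 7.0), years)
        assert trend.slope[0, 0] == 0.0
        assert np.isnan(trend.p_value[0, 0])
        assert not trend.significant[0, 0]

    def test_too_few_points_masked(self):
        trend = bs.fit_trend(np.array([1.0, 2.0]), np.array([2000, 2001]))
        assert np.isnan(trend.slope[0, 0])
        assert not trend.significant[0, 0]

    def test_noisy_series_matches_linregress_oracle(self, rng):
        """Vectorised OLS equals scipy.stats.linregress per pixel."""
        years = np.arange(1981, 2021)
        series = 0.02 * years[:, None, None] + rng.normal(0, 1.5, (40, 4, 5))
        trend = bs.fit_trend(series, years)
        for i in range(4):
            for j in range(5):
                ref = stats.linregress(years, series[:, i, j])
                assert trend.slope[i, j] == pytest.approx(ref.slope, abs=1e-10)
                # intercept is the line at calendar year 0: cancellation
                # amplifies rounding, so compare a touch looser
                assert trend.intercept[i, j] == pytest.approx(ref.intercept, abs=1e-6)
                assert trend.p_value[i, j] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_alpha_screening(self, rng):
        years = np.arange(1981, 2021)
        series = rng.normal(0, 1.0, (40, 50, 50))
        trend = bs.fit_trend(series, years, alpha=0.1)
        frac = trend.significant.mean()
        se = np.sqrt(0.1 * 0.9 / 2500)
        assert abs(frac - 0.1) < 5 * se


class TestExtrapolate:
    def _metric(self, grid, value=1500.0):
        return bs.ClimateMetricMap("map", np.full(grid.shape, value), grid)

    def test_zero_slope_unchanged(self, small_grid):
        years = np.arange(1981, 2021)
        series = np.full((40,) + small_grid.shape, 1500.0)
        trend = bs.fit_trend(series, years, small_grid)
        out = bs.extrapolate_to_2050(trend, self._metric(small_grid))
        np.testing.assert_allclose(out.values, 1500.0)

    def test_magnitude_guard_fires(self, small_grid):
        years = np.arange(1981, 2021)
        series = -30.0 * (years - 1981)[:, None, None] + np.zeros((40,) + small_grid.shape)
        trend = bs.fit_trend(series, years, small_grid)
        with pytest.raises(ValueError, match="guard"):
            bs.extrapolate_to_2050(trend, self._metric(small_grid))

    def test_noise_free_trend_extrapolates_to_line_value(self, small_grid):
        years = np.arange(1981, 2021)
        slope = -3.0
        series = 1850.0 + slope * (years - 2020)[:, None, None] + np.zeros(
            (40,) + small_grid.shape
        )
        trend = bs.fit_trend(series, years, small_grid)
        base = self._metric(small_grid, 1850.0)
        out = bs.extrapolate_to_2050(trend, base)
        np.testing.assert_allclose(out.values, 1850.0 + slope * 30, atol=1e-6)


class TestDroughtEvents:
    def test_constant_series_no_events(self):
        series = np.full((18, 2, 2), -200.0)
        events = bs.detect_drought_events(series)
        np.testing.assert_array_equal(events, 0)

    def test_two_anomalous_years_counted(self):
        """18-year series, reference mean -200 / sd 50: years at -330 are
        beyond the 2-sd anomaly (-300) and count as events."""
        series = np.full((18, 1, 1), -200.0)
        series[3], series[11] = -330.0, -330.0
        cfg = bs.DroughtConfig(reference_mean=-200.0, reference_sd=50.0)
        events = bs.detect_drought_events(series, cfg)
        assert events[0, 0] == 2

    def test_events_capped_at_five(self):
        series = np.full((18, 1, 1), -200.0)
        series[:7] = -400.0
        cfg = bs.DroughtConfig(reference_mean=-200.0, reference_sd=50.0)
        assert bs.detect_drought_events(series, cfg)[0, 0] == 5

    def test_window_selection(self):
        years = np.arange(1990, 2020)
        series = np.full((30, 1, 1), -200.0)
        series[0] = -1000.0  # outside the 2001-2018 window
        cfg = bs.DroughtConfig(reference_mean=-200.0, reference_sd=50.0)
        events = bs.detect_drought_events(series, cfg, years=years)
        assert events[0, 0] == 0
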