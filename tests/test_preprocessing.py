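"""Smoothing, filtering, detrending, z-scoring, radiation and aggregation."""

import numpy as np
import pandas as pd
import pytest

import stabdim as sd
from stabdim.errors import (
    DegeneratePixelError,
    InsufficientDataError,
    InvalidArgumentError,
)
from stabdim.preprocessing import (
    daylight_hours,
    extraterrestrial_radiation,
    prepare_periods,
    select_period,
)

from conftest import grid


class TestSavitzkyGolay:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(30, dtype=float)
        series = grid([0.5 * t**2 - 3 * t + 1, t**2 + 2])
        out = sd.savitzky_golay_smooth(series, window=5, polyorder=2)
        np.testing.assert_allclose(out.values, series.values, atol=1e-9)

    def test_constant_series_unchanged(self):
        series = grid([np.full(24, 0.4)])
        out = sd.savitzky_golay_smooth(series, window=7, polyorder=2)
        np.testing.assert_allclose(out.values, series.values, atol=1e-12)

    def test_spike_damped_and_interior_matches_bruteforce(self):
        """A single spike shrinks, and the interior output equals a sliding
        least-squares polynomial fit evaluated at the window centre."""
        t = np.arange(40, dtype=float)
        y = np.sin(t / 6)
        y[20] += 1.0
        series = grid([y])
        out = sd.savitzky_golay_smooth(series, window=5, polyorder=2).values[0]
        smooth_ref = np.sin(t / 6)
        assert abs(out[20] - smooth_ref[20]) < abs(y[20] - smooth_ref[20])
        for i in range(2, 38):  # brute-force local polyfit oracle
            coeffs = np.polyfit(t[i - 2 : i + 3], y[i - 2 : i + 3], 2)
            assert out[i] == pytest.approx(np.polyval(coeffs, t[i]), abs=1e-9)

    @pytest.mark.parametrize("window,polyorder", [(4, 2), (5, 5), (5, 7)])
    def test_invalid_window_rejected(self, window, polyorder):
        with pytest.raises(InvalidArgumentError):
            sd.savitzky_golay_smooth(grid([np.ones(30)]), window, polyorder)


class TestLowNdviFilter:
    def test_all_above_threshold_keeps_everything(self):
        series = grid(np.full((4, 24), 0.3))
        assert sd.filter_low_ndvi(series).all()

    def test_pixel_below_threshold_removed(self):
        series = grid(np.vstack([np.full(24, 0.05), np.full(24, 0.5)]))
        mask = sd.filter_low_ndvi(series)
        assert not mask.iloc[0] and mask.iloc[1]

    def test_toy_grid_retains_constructed_count(self):
        """10 pixels, 3 dipping below 0.1 in exactly one year -> 7 retained."""
        values = np.full((10, 36), 0.4)
        values[0, 12:24] = 0.05
        values[5, 0:12] = 0.09
        values[9, 24:36] = 0.0
        mask = sd.filter_low_ndvi(grid(values))
        assert int(mask.sum()) == 7
        assert set(mask.index[~mask]) == {0, 5, 9}

    def test_tightening_threshold_shrinks_retained_set(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.05, 0.4, size=(50, 24))
        series = grid(values)
        kept = [
            set(sd.filter_low_ndvi(series, threshold=th).pipe(lambda m: m.index[m]))
            for th in (0.08, 0.15, 0.25)
        ]
        assert kept[2] <= kept[1] <= kept[0]


class TestDetrend:
    def test_exact_line_gives_zero_residuals(self):
        series = grid([np.zeros(36)])
        t = (pd.DatetimeIndex(series.time.values) - series.time.values[0]).days.to_numpy() / 365.25
        series = grid([2.0 * t + 1.0])
        resid, slope, intercept = sd.detrend_linear(series)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-10)
        assert slope[0] == pytest.approx(2.0, abs=1e-10)
        assert intercept[0] == pytest.approx(1.0, abs=1e-10)

    def test_white_noise_has_no_trend(self):
        rng = np.random.default_rng(1)
        series = grid([rng.standard_normal(120)])
        _, slope, _ = sd.detrend_linear(series)
        se = 1.0 / np.sqrt(np.sum((np.arange(120) / 12 - 119 / 24) ** 2))
        assert abs(slope[0]) < 3 * se

    def test_trend_in_ar_noise_matches_closed_form_ols(self):
        rng = np.random.default_rng(2)
        noise = np.zeros(108)
        for i in range(1, 108):
            noise[i] = 0.6 * noise[i - 1] + rng.standard_normal()
        t_years = np.arange(108) / 12.0
        y = 0.12 * t_years + 0.1 * noise
        series = grid([y])
        resid, slope, intercept = sd.detrend_linear(series)
        t = (pd.DatetimeIndex(series.time.values) - series.time.values[0]).days.to_numpy() / 365.25
        closed = np.sum((t - t.mean()) * (y - y.mean())) / np.sum((t - t.mean()) ** 2)
        assert slope[0] == pytest.approx(closed, abs=1e-12)
        assert resid.values.mean() == pytest.approx(0.0, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            sd.detrend_linear(grid([[1.0, 2.0]]))


class TestZscore:
    def test_unit_moments_and_roundtrip(self):
        rng = np.random.default_rng(3)
        series = grid(rng.uniform(0, 1, size=(5, 60)))
        anom = sd.anomalies(series)
        np.testing.assert_allclose(anom.values.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(
            anom.values.values.std(axis=1, ddof=1), 1.0, atol=1e-10
        )
        np.testing.assert_allclose(anom.inverse().values, series.values, atol=1e-12)

    def test_simple_sequence(self):
        anom = sd.zscore_anomalies(grid([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(anom.values.values, [[-1.0, 0.0, 1.0]])

    def test_constant_pixel_named_in_error(self):
        with pytest.raises(DegeneratePixelError, match="pixel 1"):
            sd.zscore_anomalies(grid([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))


class TestFaoRadiation:
    def test_clear_and_overcast_bounds(self):
        ra = extraterrestrial_radiation(35.0, 100)
        n_max = daylight_hours(35.0, 100)
        assert sd.fao_radiation_from_sunshine(n_max, 35.0, 100) == pytest.approx(
            0.75 * ra
        )
        assert sd.fao_radiation_from_sunshine(0.0, 35.0, 100) == pytest.approx(
            0.25 * ra
        )

    def test_monotone_in_sunshine(self):
        n = np.linspace(0, daylight_hours(30.0, 200), 20)
        rs = sd.fao_radiation_from_sunshine(n, 30.0, np.full(20, 200))
        assert np.all(np.diff(rs) > 0)

    def test_ra_matches_independent_fao56_oracle(self):
        """Ra at 20 degrees south on day 246, re-derived step by step from the
        declination / sunset-hour-angle / inverse-distance equations."""
        lat, doy = -20.0, 246
        # independent oracle, written out long-hand
        phi = np.pi / 180 * lat
        dr = 1 + 0.033 * np.cos(2 * np.pi * doy / 365)
        decl = 0.409 * np.sin(2 * np.pi * doy / 365 - 1.39)
        ws = np.arccos(-np.tan(phi) * np.tan(decl))
        ra_oracle = (
            (24 * 60 / np.pi)
            * 0.0820
            * dr
            * (ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
        )
        assert ra_oracle == pytest.approx(32.2, abs=0.1)  # handbook value
        assert extraterrestrial_radiation(lat, doy) == pytest.approx(
            ra_oracle, abs=0.1
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.fao_radiation_from_sunshine(25.0, 35.0, 100)  # n > N
        with pytest.raises(InvalidArgumentError):
            sd.fao_radiation_from_sunshine(5.0, 70.0, 100)  # polar


class TestAggregate:
    def test_daily_precip_sums_to_monthly(self):
        days = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        series = grid(np.ones((1, len(days))), start="2001-01-01", freq="D")
        monthly = sd.aggregate(series, "monthly", "sum")
        assert monthly.sizes["time"] == 12
        assert monthly.values[0, 0] == 31.0
        assert monthly.values[0, 1] == 28.0

    def test_constant_temperature_mean_preserved(self):
        series = grid(np.full((2, 365), 10.0), start="2001-01-01", freq="D")
        monthly = sd.aggregate(series, "monthly", "mean")
        np.testing.assert_allclose(monthly.values, 10.0)

    def test_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(4)
        days = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        values = rng.standard_normal((3, len(days)))
        series = grid(values, start="2001-01-01", freq="D")
        monthly = sd.aggregate(series, "monthly", "mean")
        for m in range(12):
            sel = days.month == m + 1
            np.testing.assert_allclose(
                monthly.values[:, m], values[:, sel].mean(axis=1), atol=1e-12
            )

    def test_partial_terminal_month_dropped(self):
        series = grid(np.ones((1, 45)), start="2001-01-01", freq="D")
        monthly = sd.aggregate(series, "monthly", "sum")
        assert monthly.sizes["time"] == 1  # February incomplete

    def test_finer_target_rejected(self):
        series = grid(np.ones((1, 36)), freq="MS")
        with pytest.raises(InvalidArgumentError):
            sd.aggregate(series, "monthly", "mean")


class TestPreparePeriods:
    def test_mask_consistent_and_detrend_idempotent(self, small_scenario):
        prepared = prepare_periods(
            small_scenario.ndvi, small_scenario.climate, small_scenario.periods
        )
        assert len(prepared) == 2
        for prep in prepared:
            n_kept = int(prep.mask.sum())
            for series in (prep.ndvi, prep.temperature, prep.precipitation, prep.radiation):
                assert series.values.sizes["pixel"] == n_kept
            # detrending the detrended z-scores changes nothing
            resid, slope, _ = sd.detrend_linear(prep.ndvi.values)
            np.testing.assert_allclose(
                resid.values, prep.ndvi.values.values, atol=1e-8
            )
            np.testing.assert_allclose(slope, 0.0, atol=1e-8)

    def test_periods_partition_time(self, small_scenario):
        p1 = select_period(small_scenario.ndvi, (2000, 2008))
        p2 = select_period(small_scenario.ndvi, (2009, 2017))
        assert p1.sizes["time"] == p2.sizes["time"] == 108
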