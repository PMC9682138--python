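"""The generator must be deterministic and reproduce its declared structure."""

import numpy as np
import pandas as pd
import pytest

import stabdim as sd
from stabdim.errors import (
    InvalidArgumentError,
    NonstationaryError,
    TooShortSeriesError,
)
from stabdim.synthetic import SPECIES, SPECIES_SHU_SHARE, _SHU_PER_HEAD


class TestLandscape:
    @pytest.mark.parametrize(
        "counties,types,pixels,expected_pixels,expected_groups",
        [(3, 2, 10, 60, 6), (1, 1, 1, 1, 1), (5, 3, 4, 60, 15)],
    )
    def test_counts(self, counties, types, pixels, expected_pixels, expected_groups):
        land = sd.make_landscape(counties, types, pixels, seed=1)
        assert land.n_pixels == expected_pixels
        assert land.n_groups() == expected_groups

    def test_every_pixel_has_one_county_and_type(self, small_landscape):
        assert small_landscape.pixels["pixel_id"].is_unique
        assert small_landscape.pixels.notna().all().all()
        assert (small_landscape.county_area_ha > 0).all()

    def test_deterministic_given_seed(self):
        a = sd.make_landscape(4, 2, 5, seed=9)
        b = sd.make_landscape(4, 2, 5, seed=9)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_group_dropout_count_matches_enumeration(self):
        """Retained groups equal a direct enumeration under the same seed."""
        land = sd.make_landscape(122, 3, 2, seed=7, group_dropout=0.4)
        observed = land.n_groups()
        rng = np.random.default_rng(7)
        expected = 0
        for _ in range(122):
            keep = rng.random(3) >= 0.4
            if not keep.any():
                rng.integers(3)
                keep_count = 1
            else:
                keep_count = int(keep.sum())
            expected += keep_count
        assert observed == expected
        assert 150 < observed < 122 * 3  # near the ~206-dataset scale

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            sd.make_landscape(*bad, seed=0)

    def test_roundtrip_through_frame(self, small_landscape):
        back = sd.Landscape.from_frame(small_landscape.to_frame())
        pd.testing.assert_frame_equal(back.pixels, small_landscape.pixels)


class TestClimate:
    def test_noise_free_series_is_periodic(self, small_landscape):
        clim = sd.simulate_climate(small_landscape, 48, seed=0, noise_sd=0.0, trend=0.0)
        for da in clim.values():
            v = da.values
            assert np.allclose(v[:, :12], v[:, 12:24])

    def test_linear_trend_recovered_from_annual_means(self, small_landscape):
        clim = sd.simulate_climate(
            small_landscape, 120, seed=0, noise_sd=0.0,
            trend={"temperature": 0.5},
        )
        annual = clim["temperature"].values[0].reshape(10, 12).mean(axis=1)
        slope = np.polyfit(np.arange(10), annual, 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-10)

    def test_bit_identical_under_same_seed(self, small_landscape):
        a = sd.simulate_climate(small_landscape, 216, seed=5)
        b = sd.simulate_climate(small_landscape, 216, seed=5)
        for var in a:
            assert np.array_equal(a[var].values, b[var].values)

    def test_precipitation_clipped_at_zero(self, small_landscape):
        clim = sd.simulate_climate(
            small_landscape, 36, seed=3, noise_sd={"precipitation": 200.0}
        )
        assert (clim["precipitation"].values >= 0).all()

    def test_too_short_series_rejected(self, small_landscape):
        with pytest.raises(TooShortSeriesError):
            sd.simulate_climate(small_landscape, 12, seed=0)


class TestNdvi:
    def test_zero_coefficients_give_zero_anomaly(self, small_landscape):
        truth = sd.synthetic.constant_ground_truth(
            small_landscape, 0, 0, 0, 0, noise_sd=0.0
        )
        clim = sd.simulate_climate(small_landscape, 48, seed=1)
        _, anom = sd.simulate_ndvi(clim, truth, return_anomaly=True)
        assert np.allclose(anom.values, 0.0)

    def test_noiseless_anomaly_satisfies_recursion(self, small_landscape):
        truth = sd.synthetic.constant_ground_truth(
            small_landscape, 0.4, 0.3, 0.1, 0.5, noise_sd=0.0
        )
        clim = sd.simulate_climate(small_landscape, 60, seed=2)
        _, anom = sd.simulate_ndvi(clim, truth, return_anomaly=True)
        ca = sd.climate_anomalies(clim)
        x = anom.values
        forcing = (
            0.4 * ca["temperature"].values
            + 0.3 * ca["precipitation"].values
            + 0.1 * ca["radiation"].values
        )
        expected = forcing[:, 1:] + 0.5 * x[:, :-1]
        np.testing.assert_allclose(x[:, 1:], expected, atol=1e-12)

    def test_noisy_refit_matches_ols_oracle(self, small_landscape):
        """Coefficients refit from simulated data agree with an explicit
        per-pixel least-squares solve and sit within 0.05 of truth."""
        truth = sd.synthetic.constant_ground_truth(
            small_landscape, 0.4, 0.3, 0.1, 0.3, noise_sd=0.1
        )
        clim = sd.simulate_climate(small_landscape, 216, seed=11)
        _, anom = sd.simulate_ndvi(clim, truth, return_anomaly=True)
        ca = sd.climate_anomalies(clim)
        fit = sd.fit_ar_climate_model(
            anom, ca["temperature"], ca["precipitation"], ca["radiation"]
        )
        # independent oracle: lstsq on the explicit design matrix, pixel 0
        x = anom.values[0]
        X = np.column_stack(
            [
                ca["temperature"].values[0, 1:],
                ca["precipitation"].values[0, 1:],
                ca["radiation"].values[0, 1:],
                x[:-1],
            ]
        )
        oracle, *_ = np.linalg.lstsq(X, x[1:], rcond=None)
        np.testing.assert_allclose(
            [fit.alpha[0], fit.beta[0], fit.gamma[0], fit.delta[0]], oracle, atol=1e-10
        )
        for est, true in ((fit.alpha, 0.4), (fit.beta, 0.3), (fit.gamma, 0.1), (fit.delta, 0.3)):
            assert np.median(np.abs(est - true)) < 0.05

    def test_nonstationary_delta_rejected(self, small_landscape):
        with pytest.raises(NonstationaryError):
            sd.GroundTruth(
                alpha=np.zeros(2), beta=np.zeros(2), gamma=np.zeros(2),
                delta=np.array([0.5, 1.0]), noise_sd=np.zeros(2), rng_seed=0,
            )

    def test_misaligned_climate_rejected(self, small_landscape):
        truth = sd.synthetic.constant_ground_truth(small_landscape)
        clim = sd.simulate_climate(small_landscape, 48, seed=1)
        clim["radiation"] = clim["radiation"].isel(time=slice(0, 36))
        with pytest.raises(sd.StabdimError):
            sd.simulate_ndvi(clim, truth)


class TestLivestock:
    years = list(range(2000, 2009))

    def test_constant_density_gives_identical_counts(self, small_landscape):
        live = sd.simulate_livestock(
            small_landscape, self.years, base_shu_density=0.5, seed=4
        )
        per_county = live.groupby("county_id")
        for _, g in per_county:
            assert (g[list(SPECIES)].nunique() == 1).all()

    def test_gi_roundtrip_within_rounding(self, small_landscape):
        """SHU recomputed from emitted integer heads matches the declared
        density within the half-head-per-species rounding bound."""
        live = sd.simulate_livestock(
            small_landscape, self.years, base_shu_density=0.5, seed=4,
            county_spread=0.0,
        )
        tol_shu = sum(0.5 * _SHU_PER_HEAD[sp] for sp in SPECIES)
        for county, g in live.groupby("county_id"):
            area = small_landscape.county_area_ha.loc[county]
            shu = sd.to_sheep_units(g[list(SPECIES)]).to_numpy()
            assert np.all(np.abs(shu - 0.5 * area) <= tol_shu)

    def test_species_shares_sum_to_one(self):
        assert sum(SPECIES_SHU_SHARE.values()) == pytest.approx(1.0)

    def test_period_specific_trends_have_expected_slope_signs(self, small_landscape):
        """Flat period 1, declining period 2: the per-period OLS slopes of the
        implied grazing intensity are (~0, < 0)."""
        years = list(range(2000, 2018))
        periods = ((2000, 2008), (2009, 2017))
        live = sd.simulate_livestock(
            small_landscape, years, base_shu_density=0.5,
            trend_per_year=[0.0, -0.02], periods=periods, seed=2,
            county_spread=0.0,
        )
        gi = sd.grazing_intensity_table(live, small_landscape.county_area_ha)
        y = np.array(years)
        for county in gi.index:
            row = gi.loc[county]
            s1 = np.polyfit(y[:9], row.iloc[:9], 1)[0]
            s2 = np.polyfit(y[9:], row.iloc[9:], 1)[0]
            assert abs(s1) < 1e-3
            assert s2 < -0.01

    def test_negative_density_rejected(self, small_landscape):
        with pytest.raises(InvalidArgumentError):
            sd.simulate_livestock(small_landscape, self.years, base_shu_density=-1)


class TestScenario:
    def test_seed_determinism_and_landscape_stability(self):
        a = sd.generate_scenario(seed=3, n_counties=2, types_per_county=2, pixels_per_group=5)
        b = sd.generate_scenario(seed=3, n_counties=2, types_per_county=2, pixels_per_group=5)
        c = sd.generate_scenario(seed=4, n_counties=2, types_per_county=2, pixels_per_group=5)
        assert np.array_equal(a.ndvi.values, b.ndvi.values)
        assert not np.array_equal(a.ndvi.values, c.ndvi.values)

    def test_ground_truth_json_roundtrip(self, tmp_path, small_landscape):
        truth = sd.draw_ground_truth(small_landscape, seed=5, latent_loading=0.6)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = sd.GroundTruth.from_json(path)
        for fieldname in ("alpha", "beta", "gamma", "delta", "noise_sd", "ndvi_mean"):
            np.testing.assert_array_equal(
                getattr(back, fieldname), getattr(truth, fieldname)
            )

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sd.preset_scenario("nope")
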