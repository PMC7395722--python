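"""Synthetic scene generator: CO2 history, climate, NDVI and truth records."""

import warnings

import numpy as np
import pytest

from vegattrib.co2 import gpp_rel
from vegattrib.synth import (CO2History, SceneConfig, gen_climate, gen_ndvi,
                             make_scene)


class TestCO2History:
    def test_1980_anchor(self, co2_history):
        assert co2_history(1980) == pytest.approx(339.0)

    def test_monotone_nondecreasing(self, co2_history):
        vals = [co2_history(y) for y in range(1960, 2021)]
        assert np.all(np.diff(vals) >= 0)

    def test_out_of_range_rejected(self, co2_history):
        with pytest.raises(ValueError):
            co2_history(1950)
        with pytest.raises(ValueError):
            co2_history(2030)

    def test_user_table_interpolates_linearly(self):
        hist = CO2History({1982: 341.0, 2015: 399.0})
        assert hist(1982) == pytest.approx(341.0)
        assert hist(2015) == pytest.approx(399.0)
        # linear interpolation oracle at an interior year
        frac = (2000 - 1982) / (2015 - 1982)
        assert hist(2000) == pytest.approx(341.0 + frac * 58.0)

    def test_decreasing_table_rejected(self):
        with pytest.raises(ValueError):
            CO2History({1980: 350.0, 2000: 340.0})


class TestGenClimate:
    def test_seed_determinism(self):
        cfg = SceneConfig(n_lat=2, n_lon=2, seed=5)
        p1, t1 = gen_climate(cfg)
        p2, t2 = gen_climate(cfg)
        assert np.array_equal(p1, p2) and np.array_equal(t1, t2)

    def test_precip_mean_within_monte_carlo_error(self):
        cfg = SceneConfig(n_lat=4, n_lon=4, seed=6, precip_mean=40.0,
                          precip_shape=2.0)
        p, _ = gen_climate(cfg)
        n = p.size  # 54y * 12 * 16 pixels > 10000 samples
        se = (40.0 / np.sqrt(2.0)) / np.sqrt(n)
        assert abs(p.mean() - 40.0) <= 3 * se

    def test_noise_free_temperature_trend_exact(self):
        cfg = SceneConfig(n_lat=1, n_lon=1, seed=0, precip_shape=0.0,
                          temp_trend=0.02, temp_noise_sd=0.0)
        _, t = gen_climate(cfg)
        annual = t[:, 0, 0].reshape(-1, 12).mean(axis=1)
        slope = np.polyfit(np.arange(annual.size), annual, 1)[0]
        assert slope == pytest.approx(0.02, abs=1e-9)

    def test_precipitation_nonnegative(self):
        cfg = SceneConfig(n_lat=2, n_lon=2, seed=7, precip_mean=5.0,
                          precip_shape=0.5)
        p, _ = gen_climate(cfg)
        assert np.all(p >= 0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(precip_mean=0.0)


class TestGenNdvi:
    def test_null_scene_constant_peaks(self):
        cfg = SceneConfig(n_lat=1, n_lon=1, seed=1, precip_shape=0.0,
                          temp_noise_sd=0.0, noise_sd=0.0, f_c4=1.0,
                          vcr_intercept=0.35)
        p, t = gen_climate(cfg)
        ndvi, truth = gen_ndvi(p, t, cfg)
        peaks = ndvi[:, 0, 0].reshape(-1, 12).max(axis=1)
        assert np.allclose(peaks[1:], peaks[1])
        assert truth.obs[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_c4_pixels_have_no_co2_response(self):
        cfg = SceneConfig(n_lat=1, n_lon=1, seed=2, precip_shape=0.0,
                          temp_noise_sd=0.0, noise_sd=0.0, f_c4=1.0)
        p, t = gen_climate(cfg)
        _, truth = gen_ndvi(p, t, cfg)
        assert truth.co2[0, 0] == 0.0
        assert truth.obs[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_lu_truth_closed_form(self):
        cfg = SceneConfig(n_lat=1, n_lon=1, seed=3, precip_shape=0.0,
                          temp_noise_sd=0.0, noise_sd=0.0, lu_trend=0.002,
                          f_c4=1.0)
        p, t = gen_climate(cfg)
        _, truth = gen_ndvi(p, t, cfg)
        assert truth.lu[0, 0] == pytest.approx(0.002 * 33)

    def test_zero_forcing_zeroes_exactly_that_component(self):
        base = dict(n_lat=1, n_lon=1, seed=4, noise_sd=0.0, temp_noise_sd=1.0,
                    precip_trend=0.2, temp_trend=0.01, lu_trend=0.001,
                    vcr_intercept=0.5, vcr_slope_t=-0.02)
        cfg = SceneConfig(**{**base, "lu_trend": 0.0})
        p, t = gen_climate(cfg)
        _, truth = gen_ndvi(p, t, cfg)
        assert truth.lu[0, 0] == 0.0
        cfg = SceneConfig(**{**base, "precip_trend": 0.0, "temp_trend": 0.0})
        p, t = gen_climate(cfg)
        _, truth = gen_ndvi(p, t, cfg)
        assert truth.cc[0, 0] == 0.0
        cfg = SceneConfig(**{**base, "f_c4": 1.0})
        p, t = gen_climate(cfg)
        _, truth = gen_ndvi(p, t, cfg)
        assert truth.co2[0, 0] == 0.0

    def test_truth_components_sum_to_observed_on_linear_scene(self):
        # noise-free, low-variability scene: Theil-Sen additivity is tight
        cfg = SceneConfig(n_lat=1, n_lon=1, seed=5, precip_shape=0.0,
                          temp_noise_sd=0.0, noise_sd=0.0, precip_trend=0.2,
                          lu_trend=0.001, vcr_intercept=0.5)
        p, t = gen_climate(cfg)
        _, truth = gen_ndvi(p, t, cfg)
        parts = truth.co2 + truth.lu + truth.cv + truth.cc
        assert truth.obs[0, 0] == pytest.approx(parts[0, 0], abs=2e-3)
        assert truth.other[0, 0] == pytest.approx(
            truth.obs[0, 0] - parts[0, 0])

    def test_values_within_physical_range(self, small_scene):
        assert small_scene.ndvi.min() >= -0.3
        assert small_scene.ndvi.max() <= 1.0

    def test_heavy_clipping_warns(self):
        cfg = SceneConfig(n_lat=1, n_lon=1, seed=6, precip_shape=0.0,
                          temp_noise_sd=0.0, noise_sd=0.0, vcr_intercept=1.5,
                          f_c4=1.0)
        p, t = gen_climate(cfg)
        with pytest.warns(UserWarning, match="clipping"):
            gen_ndvi(p, t, cfg)


class TestMakeScene:
    def test_bit_identical_regeneration(self):
        cfg = SceneConfig(n_lat=2, n_lon=2, seed=11, noise_sd=0.01)
        a = make_scene(cfg)
        b = make_scene(cfg)
        assert np.array_equal(a.ndvi, b.ndvi)
        assert np.array_equal(a.truth.obs, b.truth.obs)

    def test_overrides_vary_forcings_per_pixel(self):
        cfg = SceneConfig(n_lat=2, n_lon=2, seed=12, noise_sd=0.0,
                          temp_noise_sd=0.0, precip_shape=0.0, f_c4=1.0)
        lu = np.array([[0.0, 0.002], [0.0, 0.0]])
        scene = make_scene(cfg, overrides={"lu_trend": lu})
        assert scene.truth.lu[0, 1] == pytest.approx(0.066)
        assert scene.truth.lu[0, 0] == 0.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SceneConfig(start_year=1975, analysis_start=1982)
        with pytest.raises(ValueError):
            SceneConfig(f_c4=2.0)
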