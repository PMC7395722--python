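"""Vegetation-climate relationship, breakpoints and the land-use component."""

import numpy as np
import pytest

from vegattrib.vcr import (BreakpointResult, SearchGrid, VCRModel,
                           accumulate_climate, detect_breakpoint, fit_vcr,
                           lu_component, refit_segmented)

YEARS = np.arange(1982, 2016)


def residual_model(resid, years=YEARS, p_acc=None):
    rng = np.random.default_rng(0)
    if p_acc is None:
        p_acc = rng.normal(100.0, 15.0, len(years))
    return VCRModel(3, 0, None, None, 0.0, 0.0, 0.0, 0.0,
                    np.asarray(years), np.asarray(resid, float),
                    p_acc=p_acc, t_acc=None)


class TestAccumulateClimate:
    def test_single_month_window_is_identity(self):
        monthly = np.arange(4 * 12, dtype=float)
        out = accumulate_climate(monthly, 1982, [1983], peak_month=7,
                                 accum_months=1, offset_months=0)
        assert out[0] == monthly[12 + 6]  # July 1983

    def test_window_crosses_year_boundary(self):
        # accum 3, offset 1, peak March -> Dec(prev) + Jan + Feb
        monthly = np.zeros(3 * 12)
        monthly[11] = 5.0   # Dec 1982
        monthly[12] = 7.0   # Jan 1983
        monthly[13] = 11.0  # Feb 1983
        out = accumulate_climate(monthly, 1982, [1983], peak_month=3,
                                 accum_months=3, offset_months=1)
        assert out[0] == pytest.approx(23.0)

    def test_constant_precip_sums_to_12c(self):
        out = accumulate_climate(np.full(5 * 12, 2.5), 1982, [1984], 12, 12, 0)
        assert out[0] == pytest.approx(30.0)

    def test_temperature_uses_mean(self):
        out = accumulate_climate(np.full(5 * 12, 20.0), 1982, [1984], 7, 4, 0,
                                 stat="mean")
        assert out[0] == pytest.approx(20.0)

    def test_insufficient_record_is_nan(self):
        out = accumulate_climate(np.full(24, 1.0), 1982, [1982], 3, 12, 0)
        assert np.isnan(out[0])


class TestFitVCR:
    def _make_pixel(self, accum=4, offset=0, coef=0.001, seed=0):
        rng = np.random.default_rng(seed)
        n_years = 54
        precip = rng.gamma(2.0, 20.0, n_years * 12)
        temp = np.full(n_years * 12, 20.0)  # zero-variance: must be dropped
        years = YEARS
        p_acc = accumulate_climate(precip, 1962, years, 7, accum, offset)
        ndvi = 0.05 + coef * p_acc
        return years, ndvi, precip, temp

    def test_noiseless_window_and_coefficient_recovery(self):
        years, ndvi, precip, temp = self._make_pixel(accum=4, offset=0)
        m = fit_vcr(years, ndvi, precip, temp, 1962, 7)
        assert (m.accum_months_p, m.offset_months_p) == (4, 0)
        assert m.coef_p == pytest.approx(0.001, abs=1e-9)
        assert m.coef_t == 0.0
        assert m.r2 == pytest.approx(1.0)

    def test_climate_independent_ndvi_has_low_r2(self):
        rng = np.random.default_rng(4)
        years, _, precip, temp = self._make_pixel()
        ndvi = rng.normal(0.3, 0.05, len(years))
        m = fit_vcr(years, ndvi, precip, temp, 1962, 7)
        assert m.r2 < 0.4

    def test_deterministic_refit(self):
        years, ndvi, precip, temp = self._make_pixel(seed=5)
        m1 = fit_vcr(years, ndvi, precip, temp, 1962, 7)
        m2 = fit_vcr(years, ndvi, precip, temp, 1962, 7)
        assert m1.coef_p == m2.coef_p and m1.r2 == m2.r2
        assert np.array_equal(m1.residuals, m2.residuals)

    def test_spurious_temperature_excluded(self):
        # temperature that is pure noise should not survive the
        # selection-corrected partial F-test
        rng = np.random.default_rng(6)
        years, ndvi, precip, _ = self._make_pixel(seed=6)
        ndvi = ndvi + rng.normal(0, 0.01, len(years))
        temp = rng.normal(20.0, 1.0, 54 * 12)
        m = fit_vcr(years, ndvi, precip, temp, 1962, 7)
        assert m.accum_months_t is None
        assert m.coef_t == 0.0

    def test_real_temperature_signal_retained(self):
        rng = np.random.default_rng(7)
        n_years = 54
        precip = rng.gamma(2.0, 20.0, n_years * 12)
        temp = rng.normal(20.0, 1.0, n_years * 12)
        p_acc = accumulate_climate(precip, 1962, YEARS, 7, 3, 0)
        t_acc = accumulate_climate(temp, 1962, YEARS, 7, 2, 0, "mean")
        ndvi = 0.05 + 0.001 * p_acc - 0.03 * t_acc + rng.normal(0, 0.005, 34)
        m = fit_vcr(YEARS, ndvi, precip, temp, 1962, 7)
        assert m.accum_months_t is not None
        assert m.coef_t == pytest.approx(-0.03, rel=0.25)

    def test_too_few_years_rejected(self):
        years, ndvi, precip, temp = self._make_pixel()
        with pytest.raises(ValueError):
            fit_vcr(years[:10], ndvi[:10], precip, temp, 1962, 7)


class TestBreakpoint:
    def test_clean_step_located_exactly(self):
        resid = np.where(YEARS >= 2000, 0.1, 0.0)
        resid = resid - resid.mean()
        bp = detect_breakpoint(residual_model(resid))
        assert bp.year == 2000
        assert bp.p_value < 0.05

    def test_linear_residuals_no_break(self):
        resid = 0.002 * (YEARS - 1998.5)
        bp = detect_breakpoint(residual_model(resid))
        assert bp.type == "none"

    def test_white_noise_false_positive_rate(self):
        rng = np.random.default_rng(12)
        n_fp = 0
        reps = 300
        for _ in range(reps):
            resid = rng.normal(0, 0.01, 34)
            bp = detect_breakpoint(residual_model(resid - resid.mean()))
            n_fp += bp.year is not None
        # nominal level 0.05 plus 2 binomial MC-SE
        assert n_fp / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)

    def test_minimum_segment_respected(self):
        resid = np.where(YEARS >= 2013, 0.3, 0.0)  # too close to the edge
        bp = detect_breakpoint(residual_model(resid - resid.mean()))
        assert bp.year is None or 1987 <= bp.year <= 2011


class TestLUComponent:
    def test_linear_residual_trend(self):
        model = residual_model(0.002 * (YEARS - 1982.0))
        lu = lu_component(model, 1982, 2015)
        assert lu.delta == pytest.approx(0.066)

    def test_zero_residuals(self):
        lu = lu_component(residual_model(np.zeros(34)), 1982, 2015)
        assert lu.delta == 0.0
        assert lu.p_value == 1.0

    def test_step_only_scene_recovers_break_magnitude(self):
        rng = np.random.default_rng(21)
        hits = []
        for _ in range(20):
            resid = -0.08 * (YEARS >= 2000) + rng.normal(0, 0.005, 34)
            resid = resid - resid.mean()
            model = residual_model(resid)
            bp = detect_breakpoint(model)
            lu = lu_component(model, 1982, 2015, bp)
            hits.append(lu.delta)
        assert np.median(hits) == pytest.approx(-0.08, abs=0.01)

    def test_step_plus_trend_captured_via_segments(self):
        resid = 0.001 * (YEARS - 1982.0) - 0.06 * (YEARS >= 2001)
        model = residual_model(resid - resid.mean())
        bp = detect_breakpoint(model)
        assert bp.year == 2001
        lu = lu_component(model, 1982, 2015, bp)
        assert lu.delta == pytest.approx(0.001 * 33 - 0.06, abs=0.01)

    def test_intercept_shift_leaves_lu_unchanged(self):
        resid = 0.0015 * (YEARS - 1998.0)
        a = lu_component(residual_model(resid), 1982, 2015)
        b = lu_component(residual_model(resid + 0.2), 1982, 2015)
        assert a.delta == pytest.approx(b.delta)


def test_segmented_refit_absorbs_step():
    resid = np.where(YEARS >= 2000, 0.1, 0.0)
    model = residual_model(resid - resid.mean())
    seg = refit_segmented(model, 2000)
    pre, post = seg.segment_intercepts
    assert post - pre == pytest.approx(0.1, abs=1e-9)
    assert np.abs(seg.residuals).max() < 1e-9
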