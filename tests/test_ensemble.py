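"""Ensemble combination: Stouffer, Fisher, agreement and consensus rules."""

import numpy as np
import pytest
from scipy import stats

from vegattrib.ensemble import (MemberResult, breakpoint_consensus,
                                combine_fisher, combine_members,
                                combine_stouffer, ipcc_agreement, mix_c3_c4)


class TestStouffer:
    def test_two_agreeing_members(self):
        # two-sided p=0.05 -> |z| = isf(0.025) = 1.95996; agreeing signs give
        # Z = 2*1.95996/sqrt(2) = 2.7718 and two-sided p = 2*sf(Z) = 0.00557
        p = combine_stouffer([0.05, 0.05], signs=[1.0, 1.0])
        z = stats.norm.isf(0.025)
        expected = 2 * stats.norm.sf(2 * z / np.sqrt(2))
        assert p == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(0.00557, abs=5e-5)

    def test_single_member_unchanged(self):
        assert combine_stouffer([0.13], signs=[1.0]) == pytest.approx(0.13)

    def test_opposing_members_cancel(self):
        p = combine_stouffer([0.05, 0.05], signs=[1.0, -1.0])
        assert p == pytest.approx(1.0)

    def test_weighted_matches_manual_formula(self):
        pvals, w, s = [0.02, 0.3], [0.75, 0.25], [1.0, 1.0]
        z = stats.norm.isf(np.array(pvals) / 2)
        Z = (np.array(w) * z).sum() / np.sqrt((np.array(w) ** 2).sum())
        assert combine_stouffer(pvals, w, s) == pytest.approx(2 * stats.norm.sf(Z))

    def test_extreme_p_clipped(self):
        assert 0.0 < combine_stouffer([0.0, 0.5]) < 1.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            combine_stouffer([0.1, 0.2], weights=[0.0, 0.0])


class TestFisher:
    def test_hand_value(self):
        # X2 = -2*ln(0.25) ~ 2.7726 on 4 df -> p ~ 0.596
        assert combine_fisher([0.5, 0.5]) == pytest.approx(0.596, abs=0.001)

    def test_all_ones(self):
        assert combine_fisher([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=12)
        assert combine_fisher(p) == pytest.approx(
            stats.combine_pvalues(p, method="fisher").pvalue)


def _member(member_id, co2, lu, pv=0.05):
    m = MemberResult(member_id=member_id)
    shape = np.shape(co2)
    for name, val in (("CO2", co2), ("LU", lu), ("CV", np.zeros(shape)),
                      ("CC", np.zeros(shape))):
        m.components[name] = np.asarray(val, float)
        m.p_values[name] = np.full(shape, pv)
    m.breakpoint_year = np.full(shape, np.nan)
    m.breakpoint_p = np.full(shape, np.nan)
    return m


class TestMixC3C4:
    def test_endpoint_fractions(self):
        a = _member(("p0", "t0", "c3"), [[0.04]], [[0.01]])
        b = _member(("p0", "t0", "c4"), [[0.0]], [[0.03]])
        m0 = mix_c3_c4(a, b, np.array([[0.0]]))
        assert m0.components["CO2"][0, 0] == pytest.approx(0.04)
        assert m0.components["LU"][0, 0] == pytest.approx(0.01)
        m1 = mix_c3_c4(a, b, np.array([[1.0]]))
        assert m1.components["LU"][0, 0] == pytest.approx(0.03)

    def test_weighted_mean_value(self):
        a = _member(("p0", "t0", "c3"), [[0.04]], [[0.04]])
        b = _member(("p0", "t0", "c4"), [[0.02]], [[0.02]])
        m = mix_c3_c4(a, b, np.array([[0.25]]))
        assert m.components["CO2"][0, 0] == pytest.approx(0.035)

    def test_mismatched_members_rejected(self):
        a = _member(("p0", "t0", "c3"), [[0.04]], [[0.01]])
        b = _member(("p1", "t0", "c4"), [[0.0]], [[0.03]])
        with pytest.raises(ValueError):
            mix_c3_c4(a, b, np.array([[0.5]]))

    def test_out_of_range_fraction_rejected(self):
        a = _member(("p0", "t0", "c3"), [[0.04]], [[0.01]])
        b = _member(("p0", "t0", "c4"), [[0.0]], [[0.03]])
        with pytest.raises(ValueError):
            mix_c3_c4(a, b, np.array([[1.2]]))


class TestIPCCAgreement:
    def test_pass_case(self):
        sig = [True] * 7 + [False] * 5
        dirs = [1, 1, 1, 1, 1, 1, -1] + [1] * 5
        assert ipcc_agreement(sig, dirs)  # 7/12 > 50%, 6/7 = 85.7% > 80%

    def test_half_significant_fails_strictly(self):
        assert not ipcc_agreement([True] * 6 + [False] * 6, [1] * 12)

    def test_direction_agreement_is_strict(self):
        sig = [True] * 8 + [False] * 4
        dirs = [1] * 6 + [-1] * 2 + [1] * 4
        assert not ipcc_agreement(sig, dirs)  # 6/8 = 75% <= 80%


class TestBreakpointConsensus:
    def test_clustered_years(self):
        years = [1995, 1995, 1996, 1994, 1995, 2005, 1995] + [np.nan] * 5
        sig = [True] * 7 + [False] * 5
        assert breakpoint_consensus(years, sig) == 1995

    def test_too_few_significant(self):
        years = [1995] * 5 + [np.nan] * 7
        sig = [True] * 5 + [False] * 7
        assert breakpoint_consensus(years, sig) is None

    def test_scattered_years(self):
        years = [1985, 1989, 1993, 1997, 2001, 2005, 2009] + [np.nan] * 5
        sig = [True] * 7 + [False] * 5
        assert breakpoint_consensus(years, sig) is None


class TestCombineMembers:
    def test_identical_members_idempotent_delta(self):
        members = [_member((f"p{i % 4}", f"t{i // 4}", "mixed"),
                           [[0.02]], [[0.01]]) for i in range(12)]
        ens = combine_members(members)
        assert ens.components["CO2"][0, 0] == pytest.approx(0.02)
        assert ens.components["LU"][0, 0] == pytest.approx(0.01)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        members = [_member((f"p{i}", "t0", "mixed"), [[rng.normal()]],
                           [[rng.normal()]], pv=float(rng.uniform(0.01, 0.9)))
                   for i in range(6)]
        a = combine_members(members, min_members=3)
        b = combine_members(members[::-1], min_members=3)
        for name in a.components:
            assert np.allclose(a.components[name], b.components[name])
            assert np.allclose(a.p_values[name], b.p_values[name],
                               equal_nan=True)

    def test_pixels_with_too_few_members_masked(self):
        members = [_member((f"p{i}", "t0", "mixed"), [[0.02]], [[0.01]])
                   for i in range(12)]
        for m in members[:8]:
            m.components["LU"][0, 0] = np.nan
        ens = combine_members(members, min_members=6)
        assert np.isnan(ens.components["LU"][0, 0])


def test_fisher_then_bh_controls_fdr_under_global_null():
    """Combined-then-corrected pipeline keeps the realized FDR at alpha."""
    from vegattrib.trends import bh_fdr
    rng = np.random.default_rng(2)
    n_pix, k, reps = 400, 12, 60
    any_rej = 0
    for _ in range(reps):
        p = rng.uniform(size=(n_pix, k))
        comb = np.array([combine_fisher(row) for row in p])
        any_rej += bh_fdr(comb, alpha=0.10).any()
    fdr = any_rej / reps  # global null: FDP is 1 iff any rejection
    assert fdr <= 0.10 + 2 * np.sqrt(0.1 * 0.9 / reps)
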