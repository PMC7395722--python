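"""Ensemble machinery: matched runs across climate datasets and pathways.

Gridded climate products disagree substantially over sparsely observed
drylands, so the attribution is run once per combination of precipitation
and temperature dataset (4 x 3 = 12 matched members) and the members are
combined. Two such ensembles are run — one assuming every plant follows the
C3 photosynthetic pathway (full CO2 response), one assuming C4 (no
response) — and merged per pixel with the local C3/C4 area fractions:
component estimates by the weighted mean, p-values by the weighted
Stouffer Z method. Across the 12 members, component deltas are averaged
and p-values combined with Fisher's method; pixels must additionally pass
an ensemble-agreement protocol (>50% of members significant, >80% of the
significant members agreeing in sign) and, for breakpoints, a consensus
rule (>50% of members with a significant break, >=80% of those inside a
three-year window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MemberResult", "EnsembleResult", "mix_c3_c4", "combine_stouffer",
           "combine_fisher", "ipcc_agreement", "breakpoint_consensus",
           "combine_members"]

COMPONENTS = ("CO2", "LU", "CV", "CC")

ALPHA_BREAK_DEFAULT = 0.05

_P_FLOOR = np.finfo(float).tiny
_P_CEIL = 1.0 - 1e-16


@dataclass
class MemberResult:
    """One pipeline run: a (precip dataset, temp dataset, pathway) member.

    Component and p-value fields are per-pixel arrays of a common shape;
    NaN marks pixels where the member failed.
    """

    member_id: tuple
    components: dict = field(default_factory=dict)   # name -> delta array
    p_values: dict = field(default_factory=dict)     # name -> p array
    breakpoint_year: np.ndarray | None = None        # NaN where none
    breakpoint_p: np.ndarray | None = None


@dataclass
class EnsembleResult:
    components: dict                 # name -> combined delta array
    p_values: dict                   # name -> combined p array
    significant: dict                # name -> BH mask (set by caller)
    agreement: dict                  # name -> agreement-protocol pass mask
    n_members: np.ndarray
    consensus_break: np.ndarray      # consensus year, NaN where none


def _clip_p(p):
    return np.clip(np.asarray(p, dtype=float), _P_FLOOR, _P_CEIL)


def combine_stouffer(p_list, weights=None, signs=None) -> float:
    """Weighted Stouffer combination of two-sided p-values.

    Each p is converted to a z-score carrying the sign of the member's
    effect (``signs``), so members with opposing effects cancel. The
    combined two-sided p comes from |Z| with Z = sum(w z) / sqrt(sum w^2).
    p-values at 0 or 1 are clipped to machine bounds.
    """
    p = _clip_p(p_list)
    k = p.size
    if k == 0:
        raise ValueError("no p-values to combine")
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be >=0 and not all zero")
    s = np.ones(k) if signs is None else np.sign(np.asarray(signs, dtype=float))
    s[s == 0] = 1.0
    z = stats.norm.isf(p / 2.0) * s
    Z = (w * z).sum() / np.sqrt((w**2).sum())
    return float(2.0 * stats.norm.sf(abs(Z)))


def combine_fisher(p_list) -> float:
    """Fisher's combined probability test: X2 = -2 sum(ln p) against
    chi-square with 2k degrees of freedom."""
    p = _clip_p(p_list)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, 2 * p.size))


def mix_c3_c4(m_c3: MemberResult, m_c4: MemberResult, f_c4) -> MemberResult:
    """Merge matched C3 and C4 pathway runs with per-pixel C4 fractions.

    Components are the weighted mean (1-f)*C3 + f*C4; p-values are
    combined per pixel by weighted Stouffer with the same weights and the
    sign of each member's delta.
    """
    if m_c3.member_id[:2] != m_c4.member_id[:2]:
        raise ValueError("mix requires matched members (same climate datasets)")
    f = np.asarray(f_c4, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("f_c4 must be in [0, 1]")
    out = MemberResult(member_id=m_c3.member_id[:2] + ("mixed",))
    for name in COMPONENTS:
        c3, c4 = m_c3.components[name], m_c4.components[name]
        out.components[name] = (1.0 - f) * c3 + f * c4
        p3, p4 = m_c3.p_values[name], m_c4.p_values[name]
        pm = np.full(np.shape(p3), np.nan)
        it = np.ndindex(np.shape(p3))
        for ix in it:
            w = np.array([1.0 - (f[ix] if f.ndim else float(f)),
                          (f[ix] if f.ndim else float(f))])
            ps, ds, ws = [], [], []
            for p, d, wt in ((p3[ix], c3[ix], w[0]), (p4[ix], c4[ix], w[1])):
                if np.isfinite(p) and wt > 0:
                    ps.append(p); ds.append(d); ws.append(wt)
            if ps:
                pm[ix] = combine_stouffer(ps, ws, ds)
        out.p_values[name] = pm
    if m_c3.breakpoint_year is not None:
        out.breakpoint_year = m_c3.breakpoint_year.copy()
        out.breakpoint_p = m_c3.breakpoint_p.copy()
    return out


def ipcc_agreement(significant_flags, directions) -> bool:
    """Ensemble significance-and-agreement protocol.

    Passes iff strictly more than half the members find a significant
    change AND strictly more than 80% of those significant members agree
    on the direction of change.
    """
    sig = np.asarray(significant_flags, dtype=bool)
    d = np.sign(np.asarray(directions, dtype=float))
    n = sig.size
    if n == 0:
        return False
    n_sig = int(sig.sum())
    if n_sig / n <= 0.5:
        return False
    ds = d[sig]
    n_pos = int((ds > 0).sum())
    n_neg = int((ds < 0).sum())
    return max(n_pos, n_neg) / n_sig > 0.8


def breakpoint_consensus(years, significant, window: int = 3):
    """Consensus breakpoint year across ensemble members.

    Requires strictly more than half the members to report a significant
    breakpoint, and at least 80% of those years to fall inside some
    ``window``-calendar-year span. The consensus year is the median of the
    in-window years (rounded to the nearer year).
    """
    years = np.asarray(years, dtype=float)
    sig = np.asarray(significant, dtype=bool)
    n = sig.size
    if n == 0 or int(sig.sum()) / n <= 0.5:
        return None
    ys = np.sort(years[sig & np.isfinite(years)])
    if ys.size / n <= 0.5:
        return None
    best = None
    for start in np.unique(ys):
        inside = ys[(ys >= start) & (ys <= start + window - 1)]
        if inside.size / ys.size >= 0.8 and (best is None or inside.size > best.size):
            best = inside
    if best is None:
        return None
    return int(round(float(np.median(best))))


def combine_members(members: list[MemberResult], *, min_members: int = 6,
                    alpha: float = 0.10, stat: str = "mean") -> EnsembleResult:
    """Combine matched ensemble members into a single attribution field.

    Component deltas are combined with the unweighted mean (or median)
    over available members. LU/CV/CC p-values are combined per pixel with
    Fisher's method; the CO2 p-value, which is not dataset-dependent, is
    combined the same way but is typically identical across members.
    Pixels with fewer than ``min_members`` contributing members are
    masked. Per-member significance at ``alpha`` feeds the agreement
    protocol and breakpoint consensus.
    """
    if not members:
        raise ValueError("no members to combine")
    shape = np.shape(next(iter(members[0].components.values())))
    n_members = np.zeros(shape, dtype=int)
    comps, pvals, agree = {}, {}, {}

    stacked = {name: np.stack([m.components[name] for m in members])
               for name in COMPONENTS}
    pstack = {name: np.stack([m.p_values[name] for m in members])
              for name in COMPONENTS}

    n_members = np.isfinite(stacked["LU"]).sum(axis=0)

    reducer = np.nanmedian if stat == "median" else np.nanmean
    for name in COMPONENTS:
        with np.errstate(invalid="ignore"):
            comps[name] = reducer(stacked[name], axis=0)
        pv = np.full(shape, np.nan)
        ag = np.zeros(shape, dtype=bool)
        for ix in np.ndindex(shape):
            ps = pstack[name][(slice(None), *ix)]
            ds = stacked[name][(slice(None), *ix)]
            ok = np.isfinite(ps) & np.isfinite(ds)
            if ok.sum() == 0:
                continue
            if name == "CO2":
                # the CO2 test does not depend on the climate dataset, so the
                # members share one Spearman p; no Fisher combination
                pv[ix] = float(np.median(ps[ok]))
            else:
                pv[ix] = combine_fisher(ps[ok])
            ag[ix] = ipcc_agreement(ps[ok] < alpha, ds[ok])
        pvals[name] = pv
        agree[name] = ag

    consensus = np.full(shape, np.nan)
    if members[0].breakpoint_year is not None:
        by = np.stack([m.breakpoint_year for m in members])
        bp = np.stack([m.breakpoint_p for m in members])
        for ix in np.ndindex(shape):
            years = by[(slice(None), *ix)]
            sig = np.isfinite(years) & (bp[(slice(None), *ix)] < ALPHA_BREAK_DEFAULT)
            c = breakpoint_consensus(np.where(np.isfinite(years), years, np.nan), sig)
            if c is not None:
                consensus[ix] = c

    low = n_members < min(min_members, len(members))
    for name in COMPONENTS:
        comps[name] = np.where(low, np.nan, comps[name])
        pvals[name] = np.where(low, np.nan, pvals[name])

    return EnsembleResult(components=comps, p_values=pvals, significant={},
                          agreement=agree, n_members=n_members,
                          consensus_break=consensus)
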