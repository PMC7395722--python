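"""Robust trend and significance machinery shared by every attribution component.

All drivers of vegetation change are expressed on a common scale: the change in
annual peak NDVI over the analysis window (``delta``), obtained by fitting a
Theil-Sen slope to an annual series and multiplying by the window factor.
Significance of monotone change is assessed with Spearman's rank correlation
against year, and field significance across pixels is controlled with the
Benjamini-Hochberg false-discovery-rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrendResult",
    "AnomalySpec",
    "theil_sen",
    "spearman_test",
    "delta_change",
    "fit_trend",
    "bh_fdr",
    "anomalies",
]

#: series shorter than this cannot support a meaningful component estimate
MIN_VALID_YEARS = 10

# exact Spearman permutation null is enumerable up to this n (8! = 40320)
_EXACT_SPEARMAN_MAX_N = 8


@dataclass(frozen=True)
class TrendResult:
    """A fitted monotone trend on an annual series.

    ``delta`` is the trend expressed as total change over the analysis
    window (slope x window factor), the unit used by every attribution
    component.
    """

    slope: float
    intercept: float
    p_value: float
    delta: float
    n_years: int
    rho: float = np.nan

    @property
    def valid(self) -> bool:
        return self.n_years >= MIN_VALID_YEARS


@dataclass(frozen=True)
class AnomalySpec:
    """Per-pixel standardization constants for climate anomaly series.

    mu_obs / sigma_obs are the mean and SD of the observed accumulated
    series; beta is its long-term (Theil-Sen) trend; n0 is the anchor year
    at which the climate-change anomaly is zero.
    """

    mu_obs: float
    sigma_obs: float
    beta: float
    n0: int

    def __post_init__(self):
        if not self.sigma_obs > 0:
            raise ValueError("sigma_obs must be > 0")


def _clean_pairs(years, values):
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(years) & np.isfinite(values)
    return years[ok], values[ok]


def theil_sen(years, values) -> tuple[float, float]:
    """Theil-Sen slope and intercept of ``values`` against ``years``.

    The slope is the median of all pairwise slopes; the intercept is the
    median of ``values - slope * years``. NaN pairs are dropped.

    Returns
    -------
    (slope, intercept)

    Raises
    ------
    ValueError
        If fewer than 3 valid pairs remain.
    """
    x, y = _clean_pairs(years, values)
    if x.size < 3:
        raise ValueError(f"Theil-Sen needs >=3 valid pairs, got {x.size}")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return float(slope), float(intercept)


def _exact_spearman_p(ranks_x: np.ndarray, ranks_y: np.ndarray, rho_obs: float) -> float:
    # two-sided permutation p: fraction of permutations of the y-ranks whose
    # |rho| is at least |rho_obs| (ties handled through average ranks)
    n = ranks_x.size
    perms = np.array(list(permutations(range(n))))
    ry = ranks_y[perms]  # (n!, n)
    rx = ranks_x - ranks_x.mean()
    ryc = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum() * (ryc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (ryc @ rx) / denom
    rhos = np.nan_to_num(rhos, nan=0.0)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_test(years, values) -> tuple[float, float]:
    """Spearman rank correlation of an annual series against year.

    Returns ``(rho, p)`` with a two-sided p-value. For very short series
    (n <= 8) the exact permutation null is enumerated; longer series use
    the t approximation, which is accurate for the record lengths used in
    trend attribution (>= 30 years).

    A series with all values tied carries no rank information and returns
    ``(0.0, 1.0)``.
    """
    x, y = _clean_pairs(years, values)
    if x.size < 5:
        raise ValueError(f"Spearman test needs >=5 valid pairs, got {x.size}")
    if np.all(y == y[0]):
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    if x.size <= _EXACT_SPEARMAN_MAX_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        p = _exact_spearman_p(rx, ry, rho)
    return float(rho), float(p)


def delta_change(slope: float, start_year: int, end_year: int, *, count_years: bool = False) -> float:
    """Convert an annual slope into total change over the analysis window.

    The default window factor is ``end_year - start_year`` (33 for
    1982-2015), i.e. the difference between the fitted expected values at
    the window ends. ``count_years=True`` multiplies by the number of years
    in the record instead (34 for 1982-2015).
    """
    factor = (end_year - start_year) + (1 if count_years else 0)
    return float(slope) * factor


def fit_trend(years, values, start_year: int, end_year: int, *, count_years: bool = False) -> TrendResult:
    """Theil-Sen + Spearman summary of an annual series.

    Convenience wrapper producing the ``TrendResult`` used throughout the
    attribution pipeline. Raises on series with <5 valid years; callers
    should additionally treat results with ``n_years < 10`` as invalid.
    """
    x, y = _clean_pairs(years, values)
    slope, intercept = theil_sen(x, y)
    rho, p = spearman_test(x, y)
    delta = delta_change(slope, start_year, end_year, count_years=count_years)
    return TrendResult(slope=slope, intercept=intercept, p_value=p,
                       delta=delta, n_years=int(x.size), rho=rho)


def bh_fdr(p_values, alpha: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR control across pixels.

    Missing (NaN) entries are excluded from the number of tests m and are
    returned as not significant. Returns a boolean array aligned with the
    input.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    rejected, _, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    out[ok] = rejected
    return out


def anomalies(series, years, spec: AnomalySpec, mode: str) -> np.ndarray:
    """Standardized climate anomaly series.

    mode='observed': z_n = (x_n - mu) / sigma
    mode='cc':       z_n = beta * (n - n0) / sigma  (series ignored beyond shape)
    mode='cv':       z_n = (x_adj_n - mu) / sigma, ``series`` being the
                     detrended accumulated climate.
    """
    x = np.asarray(series, dtype=float)
    n = np.asarray(years, dtype=float)
    if mode == "observed" or mode == "cv":
        return (x - spec.mu_obs) / spec.sigma_obs
    if mode == "cc":
        return spec.beta * (n - spec.n0) / spec.sigma_obs
    raise ValueError(f"unknown anomaly mode {mode!r}")
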