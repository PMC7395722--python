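"""CO2-fertilization adjustment of NDVI.

Rising atmospheric CO2 increases the water-use efficiency of C3 plants, which
in water-limited ecosystems translates into more foliage cover per unit of
rainfall. The long-term photosynthetic response is modelled with the
RuBP-regeneration-limited assimilation ratio

    GPP_rel(c_a) = [(c_a - G*) (c_a0 + 2 G*)] / [(c_a + 2 G*) (c_a0 - G*)]

where ``c_a`` is the atmospheric CO2 concentration, ``c_a0`` the baseline
concentration (1980, ~339 umol/mol) and ``G*`` the CO2 compensation point in
the absence of dark respiration (40 umol/mol). Assuming NPP is proportional
to NDVI and the GPP:Ra ratio is stable, the observed NDVI relates to a
CO2-free counterfactual by NDVI_obs / NDVI_adj = GPP_rel, so dividing the
observed series by the ratio removes the fertilization signal. C4 plants are
assumed not to respond; mixed pixels use the C3/C4 area-fraction-weighted
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trends import TrendResult, fit_trend

__all__ = ["CO2Params", "gpp_rel", "response_ratio", "adjust_series", "co2_component"]


@dataclass(frozen=True)
class CO2Params:
    """Parameters of the CO2 response: baseline concentration ``c_a0``
    (umol/mol), compensation point ``gamma_star`` (umol/mol), photosynthetic
    pathway mode and, for mixed pixels, the C4 fraction."""

    c_a0: float = 339.0
    gamma_star: float = 40.0
    response_mode: str = "c3"  # {"c3", "c4", "mixed"}
    f_c4: float = 0.0

    def __post_init__(self):
        if not self.c_a0 > self.gamma_star > 0:
            raise ValueError("require c_a0 > gamma_star > 0")
        if not 0.0 <= self.f_c4 <= 1.0:
            raise ValueError("f_c4 must be in [0, 1]")
        if self.response_mode not in ("c3", "c4", "mixed"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")


def gpp_rel(c_a, params: CO2Params = CO2Params()):
    """Relative CO2 assimilation rate at concentration ``c_a``.

    Equals 1 at the baseline concentration and increases monotonically
    with ``c_a``. Accepts scalars or arrays; raises if any concentration
    is at or below the compensation point, where the ratio is undefined.
    """
    c_a = np.asarray(c_a, dtype=float)
    if np.any(c_a <= params.gamma_star):
        raise ValueError("c_a must exceed gamma_star")
    g = params.gamma_star
    out = ((c_a - g) * (params.c_a0 + 2 * g)) / ((c_a + 2 * g) * (params.c_a0 - g))
    return float(out) if out.ndim == 0 else out


def response_ratio(c_a, params: CO2Params):
    """Pathway-aware NDVI scaling ratio R(y).

    c3: the full GPP_rel ratio; c4: 1 (no response); mixed: the
    area-weighted blend (1 - f_c4) * GPP_rel + f_c4.
    """
    if params.response_mode == "c4":
        return np.ones_like(np.asarray(c_a, dtype=float))
    r = gpp_rel(c_a, params)
    if params.response_mode == "mixed":
        r = (1.0 - params.f_c4) * np.asarray(r) + params.f_c4
    return r


def adjust_series(values, years, co2_series, params: CO2Params):
    """Remove the CO2-fertilization signal from an NDVI series.

    ``co2_series`` maps calendar year -> concentration (a dict or callable).
    Works on annual peak series or on monthly series (pass the calendar
    year of each sample). Negative NDVI values pass through the division
    unchanged in form; such bare-soil pixels are handled by the aridity
    masks downstream.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years)
    if callable(co2_series):
        conc = np.array([co2_series(int(y)) for y in years], dtype=float)
    else:
        missing = [int(y) for y in np.unique(years) if int(y) not in co2_series]
        if missing:
            raise KeyError(f"CO2 concentration missing for years: {missing}")
        conc = np.array([co2_series[int(y)] for y in years], dtype=float)
    r = response_ratio(conc, params)
    return values / r


def co2_component(obs_values, adj_values, years, start_year: int, end_year: int,
                  *, count_years: bool = False) -> TrendResult:
    """CO2-attributed change in peak NDVI.

    The fertilization component is the trend in the difference between the
    observed peak NDVI and its CO2-free counterfactual (obs - adj),
    summarized as a Theil-Sen delta with Spearman significance.
    """
    diff = np.asarray(obs_values, dtype=float) - np.asarray(adj_values, dtype=float)
    if np.allclose(np.nan_to_num(diff), 0.0):
        # no fertilization signal at all (e.g. pure C4): delta exactly 0
        n = int(np.isfinite(diff).sum())
        return TrendResult(slope=0.0, intercept=0.0, p_value=1.0, delta=0.0,
                           n_years=n, rho=0.0)
    return fit_trend(years, diff, start_year, end_year, count_years=count_years)
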