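"""Per-member attribution pipeline: NDVI + one climate pairing -> components.

A member takes the monthly NDVI grid and one precipitation/temperature
dataset pairing, and for every pixel: builds the annual peak series,
removes (C3 pathway) or keeps (C4) the CO2-fertilization signal, fits the
vegetation-climate relationship, tests for a structural break, and produces
the four component deltas with their p-values.
"""

from __future__ import annotations

import numpy as np

from . import phenology
from .climate import climate_components
from .co2 import CO2Params, adjust_series, co2_component
from .ensemble import MemberResult
from .trends import fit_trend
from .vcr import SearchGrid, detect_breakpoint, fit_vcr, lu_component, refit_segmented

__all__ = ["run_member", "observed_trend"]


def observed_trend(ndvi_monthly, start_year: int, analysis_start: int,
                   analysis_end: int, peak_month=None, *, count_years=False):
    """Observed change in peak NDVI per pixel (Theil-Sen delta + Spearman p).

    Returns (delta grid, p grid, peak-month grid)."""
    nlat, nlon = ndvi_monthly.shape[1:]
    delta = np.full((nlat, nlon), np.nan)
    pval = np.full((nlat, nlon), np.nan)
    peaks = np.zeros((nlat, nlon), dtype=int)
    for i in range(nlat):
        for j in range(nlon):
            pm = None if peak_month is None else int(np.asarray(peak_month)[i, j])
            ann = phenology.ndvi_max_annual(ndvi_monthly[:, i, j], start_year,
                                            analysis_start, analysis_end, pm)
            peaks[i, j] = ann.peak_month
            vals = ann.masked_values()
            if np.isfinite(vals).sum() < 10:
                continue
            tr = fit_trend(ann.years, vals, analysis_start, analysis_end,
                           count_years=count_years)
            delta[i, j], pval[i, j] = tr.delta, tr.p_value
    return delta, pval, peaks


def run_member(member_id, ndvi_monthly, precip_monthly, temp_monthly,
               start_year: int, analysis_start: int, analysis_end: int,
               co2_series, pathway: str = "c3", peak_month=None,
               search: SearchGrid = SearchGrid(), *,
               count_years: bool = False) -> MemberResult:
    """Run the full attribution for one ensemble member.

    ``pathway`` 'c3' applies the CO2 adjustment to the full monthly NDVI
    series before phenology; 'c4' assumes no CO2 response (identity).
    Pixels where any stage fails are left as NaN for this member.
    """
    nlat, nlon = ndvi_monthly.shape[1:]
    shape = (nlat, nlon)
    out = MemberResult(member_id=tuple(member_id))
    for name in ("CO2", "LU", "CV", "CC"):
        out.components[name] = np.full(shape, np.nan)
        out.p_values[name] = np.full(shape, np.nan)
    out.breakpoint_year = np.full(shape, np.nan)
    out.breakpoint_p = np.full(shape, np.nan)

    n_months = ndvi_monthly.shape[0]
    month_years = start_year + np.arange(n_months) // 12
    params = CO2Params(response_mode="c3" if pathway == "c3" else "c4")

    for i in range(nlat):
        for j in range(nlon):
            try:
                pm = None if peak_month is None else int(np.asarray(peak_month)[i, j])
                obs_ann = phenology.ndvi_max_annual(
                    ndvi_monthly[:, i, j], start_year,
                    analysis_start, analysis_end, pm)
                pm = obs_ann.peak_month

                # CO2 adjustment on the full monthly series, then phenology
                adj_monthly = adjust_series(ndvi_monthly[:, i, j], month_years,
                                            co2_series, params)
                adj_ann = phenology.ndvi_max_annual(
                    adj_monthly, start_year, analysis_start, analysis_end, pm)

                co2c = co2_component(obs_ann.masked_values(),
                                     adj_ann.masked_values(), obs_ann.years,
                                     analysis_start, analysis_end,
                                     count_years=count_years)
                out.components["CO2"][i, j] = co2c.delta
                out.p_values["CO2"][i, j] = co2c.p_value

                model = fit_vcr(adj_ann.years, adj_ann.masked_values(),
                                precip_monthly[:, i, j], temp_monthly[:, i, j],
                                start_year, pm, search)
                if not model.valid:
                    continue
                bp = detect_breakpoint(model)
                model.breakpoint = bp
                lu_model = model
                if bp.type == "vcr_break":
                    lu_model = refit_segmented(model, bp.year)
                    lu_model.breakpoint = bp
                lu = lu_component(lu_model, analysis_start, analysis_end, bp,
                                  count_years=count_years)
                out.components["LU"][i, j] = lu.delta
                out.p_values["LU"][i, j] = lu.p_value
                if bp.year is not None:
                    out.breakpoint_year[i, j] = bp.year
                    out.breakpoint_p[i, j] = bp.p_value

                cc = climate_components(lu_model, precip_monthly[:, i, j],
                                        temp_monthly[:, i, j], start_year, pm,
                                        analysis_start, analysis_end,
                                        count_years=count_years)
                out.components["CV"][i, j] = cc.delta_cv.delta
                out.p_values["CV"][i, j] = cc.delta_cv.p_value
                out.components["CC"][i, j] = cc.delta_cc.delta
                out.p_values["CC"][i, j] = cc.delta_cc.p_value
            except (ValueError, np.linalg.LinAlgError):
                continue
    return out
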