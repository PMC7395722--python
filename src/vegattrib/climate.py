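"""Separation of climate-driven NDVI change into change vs. variability.

The VCR captures the total climate-driven vegetation signal. To split it,
the observed accumulated climatology (computed back to 1962 so the smoother
can fill the full analysis window) is smoothed with a 20-year leading-edge
moving mean: the value for a year is the mean of that year and the 19 years
before it, which removes interannual variability while retaining the
long-term (climate-change) trajectory. The Theil-Sen slope of the smoothed
series defines the climate-change trend beta; subtracting
``beta * (n - n0)`` from the observed climatology (anchored at the analysis
start, n0 = 1982) yields the detrended, variability-only climatology.
Pushing both climatologies through the fitted VCR gives NDVI_CL (total
climate-driven) and NDVI_CV (variability-driven); their difference is the
climate-change-driven series NDVI_CC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trends import TrendResult, fit_trend, theil_sen
from .vcr import VCRModel, accumulate_climate

__all__ = ["ClimateComponents", "smooth_leading", "detrend_climate",
           "climate_components", "accumulated_climatology"]

SMOOTH_WINDOW_YEARS = 20


@dataclass
class ClimateComponents:
    years: np.ndarray
    ndvi_cl: np.ndarray
    ndvi_cv: np.ndarray
    ndvi_cc: np.ndarray
    delta_cc: TrendResult
    delta_cv: TrendResult
    beta_p: float
    beta_t: float | None


def smooth_leading(values, years, window: int = SMOOTH_WINDOW_YEARS):
    """20-year leading-edge moving mean of an annual series.

    The smoothed value for year y is the mean of years y-(window-1)..y.
    Only complete windows are returned (no shrinking windows), so the
    record must start at least window-1 years before the first output
    year; raise otherwise so callers know to extend the record
    (delta-bias correction against a longer donor dataset).
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    if values.size < window:
        raise ValueError(
            f"record of {values.size} years cannot fill a {window}-year "
            "smoothing window; extend the record (delta-bias correction)")
    kernel = np.ones(window) / window
    sm = np.convolve(values, kernel, mode="valid")
    return sm, years[window - 1:]


def detrend_climate(observed, years, smoothed, smoothed_years, n0: int):
    """Remove the climate-change trend from an observed climatology.

    beta is the Theil-Sen slope of the smoothed series; the detrended
    series is ``x_n - beta * (n - n0)`` with ``n0`` the analysis start
    year, so climate-change anomalies are zero at the anchor. Interannual
    variability is fully retained.

    Returns (detrended over ``years``, beta).
    """
    observed = np.asarray(observed, dtype=float)
    years = np.asarray(years, dtype=int)
    beta, _ = theil_sen(smoothed_years, smoothed)
    detrended = observed - beta * (years - n0)
    return detrended, float(beta)


def accumulated_climatology(monthly, clim_start_year: int, peak_month: int,
                            model: VCRModel, which: str, years):
    """Accumulated climate series on the VCR's optimal windows for ``which``
    driver ('p' or 't'); None when the model dropped temperature."""
    if which == "p":
        return accumulate_climate(monthly, clim_start_year, years, peak_month,
                                  model.accum_months_p, model.offset_months_p, "sum")
    if model.accum_months_t is None:
        return None
    return accumulate_climate(monthly, clim_start_year, years, peak_month,
                              model.accum_months_t, model.offset_months_t, "mean")


def climate_components(model: VCRModel, precip_monthly, temp_monthly,
                       clim_start_year: int, peak_month: int,
                       analysis_start: int, analysis_end: int,
                       *, count_years: bool = False,
                       window: int = SMOOTH_WINDOW_YEARS) -> ClimateComponents:
    """Decompose the climate-driven NDVI signal into CC and CV components.

    The observed climatology is accumulated on the VCR's optimal windows
    over the full climate record, smoothed and detrended per driver, and
    both the observed and detrended climatologies are evaluated through
    the VCR (climate coefficients only — structural-break intercepts are
    excluded so land-use steps cannot leak into the climate components).
    """
    clim_years = np.arange(clim_start_year + 1, analysis_end + 1)
    analysis = np.arange(analysis_start, analysis_end + 1)
    sel = np.isin(clim_years, analysis)

    def per_driver(monthly, which):
        obs_full = accumulated_climatology(monthly, clim_start_year, peak_month,
                                           model, which, clim_years)
        if obs_full is None:
            return None, None, None
        ok = np.isfinite(obs_full)
        sm, sm_years = smooth_leading(obs_full[ok], clim_years[ok], window=window)
        # beta from the smoothed series restricted to the analysis window
        in_win = (sm_years >= analysis_start) & (sm_years <= analysis_end)
        det, beta = detrend_climate(obs_full[ok][np.isin(clim_years[ok], analysis)],
                                    analysis, sm[in_win], sm_years[in_win],
                                    analysis_start)
        obs = obs_full[sel]
        return obs, det, beta

    p_obs, p_det, beta_p = per_driver(precip_monthly, "p")
    t_obs, t_det, beta_t = per_driver(temp_monthly, "t")

    ndvi_cl = model.predict_climate(p_obs, t_obs)
    ndvi_cv = model.predict_climate(p_det, t_det)
    ndvi_cc = ndvi_cl - ndvi_cv

    if np.allclose(ndvi_cc, 0.0):
        delta_cc = TrendResult(0.0, 0.0, 1.0, 0.0, analysis.size, 0.0)
    else:
        delta_cc = fit_trend(analysis, ndvi_cc, analysis_start, analysis_end,
                             count_years=count_years)
    delta_cv = fit_trend(analysis, ndvi_cv, analysis_start, analysis_end,
                         count_years=count_years)
    return ClimateComponents(years=analysis, ndvi_cl=ndvi_cl, ndvi_cv=ndvi_cv,
                             ndvi_cc=ndvi_cc, delta_cc=delta_cc, delta_cv=delta_cv,
                             beta_p=beta_p, beta_t=beta_t)
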