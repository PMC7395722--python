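"""TSS-RESTREND core: the per-pixel Vegetation-Climate Relationship (VCR).

Dryland peak NDVI is driven primarily by the rainfall accumulated over the
months leading into the growing-season peak, with a secondary temperature
influence. The VCR is an ordinary least-squares regression of the
(CO2-adjusted) annual peak NDVI on precipitation and temperature accumulated
over per-pixel optimal windows, found by exhaustive search over accumulation
lengths and offsets. Land-use impacts appear in the residuals of this
regression: gradual impacts as a residual trend, abrupt ones (deforestation,
policy change, fire) as structural breakpoints. Breakpoint candidates are
located with a CUSUM scan of the residuals and confirmed with a Chow F-test;
a confirmed break in the regression itself triggers a segmented refit with
separate intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trends import delta_change

__all__ = ["SearchGrid", "VCRModel", "BreakpointResult", "accumulate_climate",
           "fit_vcr", "detect_breakpoint", "lu_component", "LUComponent"]

ALPHA_BREAK = 0.05
MIN_SEGMENT_YEARS = 5
COLLINEARITY_LIMIT = 0.95
MIN_FIT_YEARS = 15


@dataclass(frozen=True)
class SearchGrid:
    """Accumulation/offset windows searched for each climate driver.

    Accumulation is the number of months summed (precipitation) or averaged
    (temperature); offset shifts the window back from the peak month. The
    defaults (1-12 month accumulation, 0-3 month offset) cover the response
    lags observed in dryland ecosystems.
    """

    accum_p: tuple = tuple(range(1, 13))
    offset_p: tuple = tuple(range(0, 4))
    accum_t: tuple = tuple(range(1, 13))
    offset_t: tuple = tuple(range(0, 4))


@dataclass(frozen=True)
class BreakpointResult:
    year: int | None
    p_value: float
    type: str  # {"vcr_break", "residual_break", "none"}


@dataclass
class VCRModel:
    """Fitted vegetation-climate relationship for one pixel."""

    accum_months_p: int
    offset_months_p: int
    accum_months_t: int | None
    offset_months_t: int | None
    coef_p: float
    coef_t: float
    intercept: float
    r2: float
    years: np.ndarray
    residuals: np.ndarray
    p_acc: np.ndarray
    t_acc: np.ndarray | None
    breakpoint: BreakpointResult | None = None
    segment_intercepts: tuple | None = None  # (pre, post) when segmented
    valid: bool = True

    def predict_climate(self, p_acc, t_acc=None) -> np.ndarray:
        """Climate-driven NDVI for given accumulated climate series.

        Uses the climate coefficients and the base intercept only; any
        segment (land-use step) intercepts are deliberately excluded so a
        structural break never leaks into the climate-driven component.
        """
        out = self.intercept + self.coef_p * np.asarray(p_acc, dtype=float)
        if self.coef_t != 0.0 and t_acc is not None:
            out = out + self.coef_t * np.asarray(t_acc, dtype=float)
        return out


def accumulate_climate(monthly, start_year: int, years, peak_month: int,
                       accum_months: int, offset_months: int,
                       stat: str = "sum") -> np.ndarray:
    """Accumulate a monthly climate record into one value per growing year.

    For each year the window covers ``accum_months`` months ending
    ``offset_months`` before the pixel's peak month (crossing the year
    boundary backwards as needed). Precipitation is summed, temperature
    averaged. Years whose window reaches before the record start are NaN.
    """
    monthly = np.asarray(monthly, dtype=float)
    years = np.asarray(years, dtype=int)
    out = np.full(years.size, np.nan)
    for i, y in enumerate(years):
        end = (int(y) - start_year) * 12 + (peak_month - 1) - offset_months
        lo = end - accum_months + 1
        if lo < 0 or end >= monthly.size:
            continue
        window = monthly[lo:end + 1]
        out[i] = window.sum() if stat == "sum" else window.mean()
    return out


def _best_windows(y, P, T):
    """Vectorized R^2 over all (precip window, temp window) pairs.

    For a two-predictor OLS with centered variables,
    R^2 = (r_yp^2 + r_yt^2 - 2 r_yp r_yt r_pt) / (1 - r_pt^2),
    so a couple of matrix products score the whole search grid at once.
    Returns (i_p, i_t, r_pt) of the best pair; i_t is None when every
    temperature pairing is degenerate.
    """
    yc = y - y.mean()
    ys = np.sqrt((yc**2).sum())
    Pc = P - P.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=1, keepdims=True)
    pn = np.sqrt((Pc**2).sum(axis=1))
    tn = np.sqrt((Tc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_yp = (Pc @ yc) / (pn * ys)
        r_yt = (Tc @ yc) / (tn * ys)
        r_pt = (Pc @ Tc.T) / np.outer(pn, tn)
        r2 = (r_yp[:, None]**2 + r_yt[None, :]**2
              - 2 * r_yp[:, None] * r_yt[None, :] * r_pt) / (1 - r_pt**2)
    r2 = np.where(np.isfinite(r2), r2, -np.inf)
    if np.all(np.isinf(r2)):
        return None, None, np.nan
    i_p, i_t = np.unravel_index(np.argmax(r2), r2.shape)
    return int(i_p), int(i_t), float(r_pt[i_p, i_t])


def _ols(X, y):
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean())**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return beta, resid, r2, ss_res


def fit_vcr(ndvi_years, ndvi_values, precip_monthly, temp_monthly,
            clim_start_year: int, peak_month: int,
            search: SearchGrid = SearchGrid()) -> VCRModel:
    """Fit the per-pixel VCR by exhaustive window search.

    Scores every precipitation x temperature accumulation/offset pairing by
    the R^2 of ``NDVI ~ P_acc + T_acc`` and refits the winner by OLS. If the
    winning pair's accumulated series are nearly collinear
    (|corr| > 0.95), temperature is dropped and the best
    precipitation-only window is used (precipitation is the primary dryland
    driver).
    """
    years = np.asarray(ndvi_years, dtype=int)
    y = np.asarray(ndvi_values, dtype=float)
    ok = np.isfinite(y)
    years, y = years[ok], y[ok]
    if years.size < MIN_FIT_YEARS:
        raise ValueError(f"VCR fit needs >={MIN_FIT_YEARS} valid years")

    p_windows = [(a, o) for a in search.accum_p for o in search.offset_p]
    t_windows = [(a, o) for a in search.accum_t for o in search.offset_t]
    P = np.array([accumulate_climate(precip_monthly, clim_start_year, years,
                                     peak_month, a, o, "sum")
                  for a, o in p_windows])
    T = np.array([accumulate_climate(temp_monthly, clim_start_year, years,
                                     peak_month, a, o, "mean")
                  for a, o in t_windows])
    # windows reaching before the climate record start disqualify themselves
    P[~np.isfinite(P).all(axis=1)] = np.nan
    T[~np.isfinite(T).all(axis=1)] = np.nan
    if np.all(np.isnan(P)):
        raise ValueError("no precipitation window fits inside the climate record")
    if np.nanmax(np.nanstd(P, axis=1)) == 0:
        m = VCRModel(0, 0, None, None, 0.0, 0.0, float(y.mean()), 0.0, years,
                     y - y.mean(), np.full(years.size, np.nan), None, valid=False)
        return m

    i_p, i_t, r_pt = _best_windows(y, P, T)

    # best precipitation-only window (by |correlation| with NDVI)
    Pc = P - P.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Pc @ yc) / (np.sqrt((Pc**2).sum(axis=1)) * np.sqrt((yc**2).sum()))
    r = np.where(np.isfinite(r), np.abs(r), -np.inf)
    i_p_only = int(np.argmax(r))
    r2_p_only = float(r[i_p_only] ** 2)
    if not np.isfinite(r[i_p_only]):
        raise ValueError("degenerate climate: VCR fit failed")

    # i_p is None when every temperature pairing is degenerate
    use_temp = i_p is not None and abs(r_pt) <= COLLINEARITY_LIMIT \
        and np.isfinite(T[i_t]).all() and np.std(T[i_t]) > 0
    if use_temp:
        # temperature must add explanatory power beyond what maximizing
        # R^2 over the temperature window grid would find in pure noise:
        # partial F-test Bonferroni-corrected for the searched windows
        n = y.size
        yj = y
        Xj = np.column_stack([np.ones(n), P[i_p], T[i_t]])
        _, _, r2_joint, _ = _ols(Xj, yj)
        df = n - 3
        num = max(r2_joint - r2_p_only, 0.0)
        f_part = (num / 1.0) / max((1.0 - r2_joint) / df, 1e-12)
        n_t_windows = int(np.isfinite(T).all(axis=1).sum()) or 1
        p_part = stats.f.sf(f_part, 1, df) * n_t_windows
        use_temp = p_part <= 0.05
    if not use_temp:
        i_p = i_p_only

    p_acc = P[i_p]
    t_acc = T[i_t] if use_temp else None
    X = np.column_stack([np.ones(years.size), p_acc] +
                        ([t_acc] if use_temp else []))
    beta, resid, r2, _ = _ols(X, y)
    a_p, o_p = p_windows[i_p]
    a_t, o_t = t_windows[i_t] if use_temp else (None, None)
    return VCRModel(
        accum_months_p=a_p, offset_months_p=o_p,
        accum_months_t=a_t, offset_months_t=o_t,
        coef_p=float(beta[1]), coef_t=float(beta[2]) if use_temp else 0.0,
        intercept=float(beta[0]), r2=float(r2),
        years=years, residuals=resid, p_acc=p_acc, t_acc=t_acc,
    )


def _chow_f(y, X_pooled, X_segmented, k_extra):
    _, _, _, rss1 = _ols(X_pooled, y)
    _, _, _, rss2 = _ols(X_segmented, y)
    n, k2 = X_segmented.shape
    df2 = n - k2
    scale = float((y**2).sum())
    if rss1 <= 1e-12 * max(scale, 1e-12):
        # the pooled model already fits perfectly: nothing to break
        return 0.0, 1.0
    if df2 <= 0 or rss2 <= 0:
        return np.inf, 0.0
    f = ((rss1 - rss2) / k_extra) / (rss2 / df2)
    p = float(stats.f.sf(max(f, 0.0), k_extra, df2))
    return f, p


def detect_breakpoint(model: VCRModel, alpha_break: float = ALPHA_BREAK,
                      min_segment: int = MIN_SEGMENT_YEARS) -> BreakpointResult:
    """Locate and test a single structural break in the VCR residuals.

    The candidate year is the most extreme point of the CUSUM of the
    demeaned residuals (constrained to leave ``min_segment`` years on each
    side) and is confirmed with a Chow F-test on the residual-vs-year
    regression. A confirmed break is then tested against the VCR regression
    itself (segment-intercept dummy): if the regression also breaks, the
    type is ``vcr_break`` and callers should refit per-segment; otherwise it
    is a ``residual_break`` (offset in vegetation not explained by climate).
    """
    years = model.years.astype(float)
    resid = model.residuals
    n = years.size
    if n < 2 * min_segment:
        return BreakpointResult(None, 1.0, "none")
    cusum = np.cumsum(resid - resid.mean())
    # break after index k: candidate must leave min_segment on both sides
    lo, hi = min_segment - 1, n - min_segment - 1
    n_candidates = hi - lo + 1
    k = lo + int(np.argmax(np.abs(cusum[lo:hi + 1])))
    by = int(model.years[k + 1])  # first year of the new segment

    seg = (years >= by).astype(float)
    X1 = np.column_stack([np.ones(n), years])
    X2 = np.column_stack([np.ones(n), years, seg, seg * years])
    _, p_raw = _chow_f(resid, X1, X2, 2)
    # the candidate was chosen as the most extreme of n_candidates scan
    # positions; Bonferroni keeps the confirmation test at nominal level
    p = min(1.0, p_raw * n_candidates)
    if p > alpha_break:
        return BreakpointResult(None, p, "none")

    # does the VCR regression itself break? (intercept dummy on the full model)
    cols = [np.ones(n), model.p_acc]
    if model.t_acc is not None:
        cols.append(model.t_acc)
    Xv1 = np.column_stack(cols)
    Xv2 = np.column_stack(cols + [seg])
    # reconstruct the fitted NDVI series: residuals + climate-fitted values
    ndvi = model.residuals + model.predict_climate(model.p_acc, model.t_acc)
    _, p_vcr = _chow_f(ndvi, Xv1, Xv2, 1)
    btype = "vcr_break" if p_vcr <= alpha_break else "residual_break"
    return BreakpointResult(by, p, btype)


def refit_segmented(model: VCRModel, break_year: int) -> VCRModel:
    """Refit the VCR with separate intercepts before/after a confirmed
    structural break (climate slopes shared across segments)."""
    years = model.years
    ndvi = model.residuals + model.predict_climate(model.p_acc, model.t_acc)
    seg = (years >= break_year).astype(float)
    cols = [np.ones(years.size), model.p_acc]
    if model.t_acc is not None:
        cols.append(model.t_acc)
    X = np.column_stack(cols + [seg])
    beta, resid, r2, _ = _ols(X, ndvi)
    new = VCRModel(
        accum_months_p=model.accum_months_p, offset_months_p=model.offset_months_p,
        accum_months_t=model.accum_months_t, offset_months_t=model.offset_months_t,
        coef_p=float(beta[1]),
        coef_t=float(beta[2]) if model.t_acc is not None else 0.0,
        intercept=float(beta[0]), r2=float(r2), years=years,
        residuals=resid, p_acc=model.p_acc, t_acc=model.t_acc,
        segment_intercepts=(float(beta[0]), float(beta[0] + beta[-1])),
    )
    return new


@dataclass(frozen=True)
class LUComponent:
    delta: float
    p_value: float
    slope: float
    break_year: int | None


def lu_component(model: VCRModel, start_year: int, end_year: int,
                 breakpoint: BreakpointResult | None = None,
                 *, count_years: bool = False,
                 alpha_break: float = ALPHA_BREAK) -> LUComponent:
    """Land-use-attributed change from the VCR residual trend.

    Without a breakpoint the component is the OLS slope of residuals
    against year times the window factor, with the slope's t-test p-value.
    With a confirmed breakpoint the residuals are fitted with separate
    segment intercepts (and separate slopes when a Chow test rejects slope
    equality), and the component is the fitted value at the window end
    minus the fitted value at the start — capturing both the step and the
    gradual trend. Significance is the regression F-test against a
    constant model.

    For a ``vcr_break`` the caller is expected to pass the segmented-refit
    model (see :func:`refit_segmented`); for a ``residual_break`` the
    original model's residuals are segmented here.
    """
    years = model.years.astype(float)
    resid = model.residuals
    n = years.size
    by = breakpoint.year if breakpoint is not None and breakpoint.year else None
    # residual step already absorbed into segment intercepts after a refit
    segmented_already = model.segment_intercepts is not None

    if by is None or segmented_already:
        X = np.column_stack([np.ones(n), years])
        beta, r, _, ss_res = _ols(X, resid)
        slope = float(beta[1])
        if np.allclose(resid, 0.0):
            out_delta = delta_change(slope, start_year, end_year, count_years=count_years)
            return LUComponent(out_delta, 1.0, slope, by)
        dof = n - 2
        sxx = ((years - years.mean())**2).sum()
        se = np.sqrt(ss_res / dof / sxx)
        t = slope / se if se > 0 else 0.0
        p = float(2 * stats.t.sf(abs(t), dof))
        delta = delta_change(slope, start_year, end_year, count_years=count_years)
        if segmented_already and by is not None:
            # add back the step captured by the segment intercepts
            pre, post = model.segment_intercepts
            delta += float(post - pre)
        return LUComponent(delta, p, slope, by)

    seg = (years >= by).astype(float)
    X_common = np.column_stack([np.ones(n), years, seg])
    X_separate = np.column_stack([np.ones(n), years, seg, seg * (years - by)])
    _, p_slope_eq = _chow_f(resid, X_common, X_separate, 1)
    X = X_separate if p_slope_eq <= alpha_break else X_common
    beta, r, _, ss_res = _ols(X, resid)

    def fitted_at(year):
        row = [1.0, year, float(year >= by)]
        if X.shape[1] == 4:
            row.append(float(year >= by) * (year - by))
        return float(np.array(row) @ beta)

    span = (end_year - start_year) + (1 if count_years else 0)
    delta = fitted_at(start_year + span) - fitted_at(start_year)

    # model-vs-constant F test
    ss_tot = float(((resid - resid.mean())**2).sum())
    k = X.shape[1] - 1
    dof = n - X.shape[1]
    if ss_res <= 0 or dof <= 0:
        p = 0.0 if ss_tot > 0 else 1.0
    else:
        f = ((ss_tot - ss_res) / k) / (ss_res / dof)
        p = float(stats.f.sf(max(f, 0.0), k, dof))
    return LUComponent(float(delta), p, float(beta[1]), by)
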