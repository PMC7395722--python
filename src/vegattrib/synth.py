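"""Synthetic dryland scenes with known, separable forcings.

The generator emulates the statistical structure of the observational
inputs — seasonal NDVI peaking in a configurable month, gamma-distributed
monthly rainfall with an optional long-term trend (the climate-change
forcing), temperature with trend and Gaussian noise, a multiplicative CO2
fertilization response applied to the C3 fraction of each pixel, and
gradual (linear trend) and abrupt (step) land-use signals — so that every
downstream attribution stage can be validated by parameter recovery against
an exact per-pixel truth record. No satellite artifacts (orbital drift,
clouds, snow) are emulated.

The annual peak NDVI of a pixel is generated as

    [b0 + cP * P_acc(y) + cT * T_acc(y) + lu * (y - y0) + step * 1{y >= yb}
       + eps_y] * [(1 - f_c4) * GPP_rel(c_a(y)) + f_c4]

clipped to the physical NDVI range, and spread over the months of each year
with a fixed seasonal shape that attains its maximum in the peak month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .co2 import CO2Params, gpp_rel
from .trends import theil_sen, delta_change
from .vcr import accumulate_climate

__all__ = ["SceneConfig", "CO2History", "TruthRecord", "gen_climate",
           "gen_ndvi", "make_scene", "Scene"]

NDVI_MIN, NDVI_MAX = -0.3, 1.0

#: default CO2 history anchors (umol/mol): only the 1980 value is pinned by
#: the baseline convention; the others track the observed historical rise
DEFAULT_CO2_TABLE = {1960: 317.0, 1980: 339.0, 2000: 369.0, 2015: 399.0}
CO2_YEAR_MIN, CO2_YEAR_MAX = 1960, 2020


class CO2History:
    """Annual atmospheric CO2 concentration, piecewise-linear in year.

    Interpolates through a user-supplied {year: concentration} table
    (default anchors above) and extrapolates linearly at the edges within
    the supported 1960-2020 range.
    """

    def __init__(self, table: dict | None = None):
        table = dict(DEFAULT_CO2_TABLE if table is None else table)
        years = np.array(sorted(table), dtype=float)
        conc = np.array([table[int(y)] for y in years], dtype=float)
        if np.any(np.diff(conc) < 0):
            raise ValueError("CO2 table must be non-decreasing in year")
        self._years, self._conc = years, conc

    def __call__(self, year) -> float:
        y = float(year)
        if not CO2_YEAR_MIN <= y <= CO2_YEAR_MAX:
            raise ValueError(f"year {year} outside supported range "
                             f"{CO2_YEAR_MIN}-{CO2_YEAR_MAX}")
        ys, cs = self._years, self._conc
        if y <= ys[0]:
            slope = (cs[1] - cs[0]) / (ys[1] - ys[0])
            return float(cs[0] + slope * (y - ys[0]))
        if y >= ys[-1]:
            slope = (cs[-1] - cs[-2]) / (ys[-1] - ys[-2])
            return float(cs[-1] + slope * (y - ys[-1]))
        return float(np.interp(y, ys, cs))

    def as_dict(self, first: int, last: int) -> dict:
        return {y: self(y) for y in range(first, last + 1)}


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of a synthetic scene (one value per field applies to
    every pixel; spatial variation comes from per-pixel overrides in
    :func:`make_scene`).

    Units: precipitation mm/month, temperature degC, NDVI dimensionless,
    trends per year. ``precip_shape`` is the gamma shape of monthly
    rainfall (smaller = drier, more dispersed); ``precip_trend`` is the
    climate-change forcing on rainfall.
    """

    n_lat: int = 8
    n_lon: int = 8
    start_year: int = 1962
    end_year: int = 2015
    analysis_start: int = 1982
    peak_month: int = 7
    precip_mean: float = 40.0
    precip_shape: float = 2.0
    precip_trend: float = 0.0
    temp_mean: float = 22.0
    temp_trend: float = 0.0
    temp_noise_sd: float = 0.5
    vcr_slope_p: float = 0.0015
    vcr_slope_t: float = -0.01
    vcr_intercept: float = 0.15
    accum_months_p: int = 3
    offset_months_p: int = 0
    accum_months_t: int = 2
    offset_months_t: int = 0
    lu_trend: float = 0.0
    break_year: int | None = None
    break_step: float = 0.0
    f_c4: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.end_year >= self.analysis_start >= self.start_year + 20):
            raise ValueError("need end_year >= analysis_start >= start_year + 20 "
                             "(the 20-year smoothing window must be fillable)")
        if self.precip_mean <= 0:
            raise ValueError("precip_mean must be positive")
        if not 0.0 <= self.f_c4 <= 1.0:
            raise ValueError("f_c4 must be in [0, 1]")
        if not 1 <= self.peak_month <= 12:
            raise ValueError("peak_month must be 1..12")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def analysis_years(self) -> np.ndarray:
        return np.arange(self.analysis_start, self.end_year + 1)


@dataclass
class TruthRecord:
    """Exact per-forcing change in peak NDVI over the analysis window.

    Each component is the Theil-Sen delta (same 33-interval convention as
    the pipeline) of the isolated noise-free forcing series, so recovery
    tests compare like with like. ``obs`` is the delta of the full
    noise-free peak series; ``other`` is the closure remainder
    obs - (co2 + lu + cv + cc), nonzero only through Theil-Sen
    non-additivity and clipping.
    """

    obs: np.ndarray
    co2: np.ndarray
    lu: np.ndarray
    cv: np.ndarray
    cc: np.ndarray
    other: np.ndarray
    clipped_fraction: float = 0.0


@dataclass
class Scene:
    config: SceneConfig
    precip: np.ndarray       # (months, lat, lon)
    temp: np.ndarray
    ndvi: np.ndarray
    truth: TruthRecord
    co2: CO2History
    peak_month: np.ndarray   # (lat, lon)


def _monthly_axis(config: SceneConfig):
    n = config.n_years * 12
    years = config.start_year + np.arange(n) // 12
    months = np.arange(n) % 12 + 1
    return years, months


def gen_climate(config: SceneConfig, rng: np.random.Generator | None = None):
    """Generate monthly precipitation and temperature grids.

    Precipitation is gamma-distributed per month with mean
    ``precip_mean + precip_trend * (year - start_year)`` (floored at a
    small positive value) and shape ``precip_shape``; temperature is
    Gaussian around ``temp_mean + temp_trend * (year - start_year)``.
    Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    years, _ = _monthly_axis(config)
    shape = (years.size, config.n_lat, config.n_lon)
    mu_p = np.maximum(config.precip_mean
                      + config.precip_trend * (years - config.start_year), 0.1)
    mu_p = np.broadcast_to(mu_p[:, None, None], shape)
    if config.precip_shape > 0:
        precip = rng.gamma(config.precip_shape, mu_p / config.precip_shape)
    else:  # dispersion -> 0: deterministic mean rainfall
        precip = mu_p.copy()
    mu_t = config.temp_mean + config.temp_trend * (years - config.start_year)
    temp = np.broadcast_to(mu_t[:, None, None], shape).copy()
    if config.temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, config.temp_noise_sd, shape)
    return precip.astype(float), temp.astype(float)


def _seasonal_shape(peak_month: int) -> np.ndarray:
    # raised-cosine over month distance from the peak; 1 at the peak,
    # strictly below 1 elsewhere so the annual max lands on the peak month
    m = np.arange(1, 13)
    d = np.minimum(np.abs(m - peak_month), 12 - np.abs(m - peak_month))
    return 0.35 + 0.65 * np.cos(np.pi * d / 6.0) ** 2 * (d < 6)


def _ts_delta(years, values, start, end):
    if np.allclose(values, values[0]):
        return 0.0
    slope, _ = theil_sen(years, values)
    return delta_change(slope, start, end)


def gen_ndvi(precip, temp, config: SceneConfig,
             rng: np.random.Generator | None = None,
             co2: CO2History | None = None):
    """Generate the monthly NDVI grid and the per-pixel truth record.

    The annual peak is assembled from the VCR linear form plus land-use
    forcings and noise, multiplied by the pathway-weighted CO2 response,
    then spread over months with the seasonal shape. Warns when clipping
    to the physical NDVI range touches more than 5% of annual peaks
    (the truth record is then no longer exact).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if co2 is None:
        co2 = CO2History()
    cfg = config
    all_years = np.arange(cfg.start_year, cfg.end_year + 1)
    ay = cfg.analysis_years
    a0, a1 = cfg.analysis_start, cfg.end_year
    nlat, nlon = cfg.n_lat, cfg.n_lon

    conc = np.array([co2(y) for y in all_years])
    r_c3 = gpp_rel(conc, CO2Params())
    r_mix = (1.0 - cfg.f_c4) * r_c3 + cfg.f_c4

    y0 = cfg.analysis_start
    lu_series = cfg.lu_trend * (all_years - y0)
    if cfg.break_year is not None:
        lu_series = lu_series + cfg.break_step * (all_years >= cfg.break_year)

    shape = _seasonal_shape(cfg.peak_month)
    n_months = all_years.size * 12
    ndvi = np.zeros((n_months, nlat, nlon))
    sel = np.isin(all_years, ay)

    obs_d = np.zeros((nlat, nlon)); co2_d = np.zeros((nlat, nlon))
    lu_d = np.zeros((nlat, nlon)); cv_d = np.zeros((nlat, nlon))
    cc_d = np.zeros((nlat, nlon)); of_d = np.zeros((nlat, nlon))
    n_clipped = 0

    # deterministic trend part of the accumulated climate (the CC forcing)
    p_trend_acc = cfg.precip_trend * cfg.accum_months_p   # mm/yr in P_acc units
    t_trend_acc = cfg.temp_trend                          # degC/yr (mean window)

    for i in range(nlat):
        for j in range(nlon):
            p_acc = accumulate_climate(precip[:, i, j], cfg.start_year, all_years,
                                       cfg.peak_month, cfg.accum_months_p,
                                       cfg.offset_months_p, "sum")
            t_acc = accumulate_climate(temp[:, i, j], cfg.start_year, all_years,
                                       cfg.peak_month, cfg.accum_months_t,
                                       cfg.offset_months_t, "mean")
            # first year's window may reach before the record: backfill with mean
            p_acc = np.where(np.isfinite(p_acc), p_acc, np.nanmean(p_acc))
            t_acc = np.where(np.isfinite(t_acc), t_acc, np.nanmean(t_acc))

            climate_series = cfg.vcr_slope_p * p_acc + cfg.vcr_slope_t * t_acc
            noise = rng.normal(0.0, cfg.noise_sd, all_years.size) \
                if cfg.noise_sd > 0 else np.zeros(all_years.size)
            bracket = cfg.vcr_intercept + climate_series + lu_series + noise
            peaks = bracket * r_mix
            clipped = np.clip(peaks, NDVI_MIN, NDVI_MAX)
            n_clipped += int((clipped != peaks).sum())

            block = clipped[:, None] * shape[None, :]
            ndvi[:, i, j] = block.reshape(-1)

            # exact truth bookkeeping on the noise-free series
            bracket_nf = bracket - noise
            obs_d[i, j] = _ts_delta(ay, (bracket_nf * r_mix)[sel], a0, a1)
            co2_d[i, j] = _ts_delta(ay, (bracket_nf * (r_mix - 1.0))[sel], a0, a1)
            lu_d[i, j] = _ts_delta(ay, lu_series[sel], a0, a1)
            cc_series = (cfg.vcr_slope_p * p_trend_acc
                         + cfg.vcr_slope_t * t_trend_acc) * (all_years - y0)
            cc_d[i, j] = _ts_delta(ay, cc_series[sel], a0, a1)
            cv_series = climate_series - (cfg.vcr_slope_p * p_trend_acc
                                          + cfg.vcr_slope_t * t_trend_acc) \
                * (all_years - cfg.start_year)
            cv_d[i, j] = _ts_delta(ay, cv_series[sel], a0, a1)
            of_d[i, j] = obs_d[i, j] - (co2_d[i, j] + lu_d[i, j]
                                        + cv_d[i, j] + cc_d[i, j])

    frac = n_clipped / (all_years.size * nlat * nlon)
    if frac > 0.05:
        warnings.warn(f"clipping affected {frac:.1%} of annual peaks; "
                      "truth record is no longer exact", stacklevel=2)
    truth = TruthRecord(obs=obs_d, co2=co2_d, lu=lu_d, cv=cv_d, cc=cc_d,
                        other=of_d, clipped_fraction=frac)
    return ndvi, truth


def make_scene(config: SceneConfig, overrides: dict | None = None,
               co2: CO2History | None = None) -> Scene:
    """Generate a full scene; ``overrides`` maps field name -> (lat, lon)
    array for per-pixel forcing variation (e.g. differing lu_trend or
    f_c4 across the scene).

    Per-pixel overrides regenerate each pixel's NDVI from the shared
    climate realization, so climate stays spatially coherent while the
    forcings vary.
    """
    if co2 is None:
        co2 = CO2History()
    rng = np.random.default_rng(config.seed)
    precip, temp = gen_climate(config, rng)
    ndvi_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    if not overrides:
        ndvi, truth = gen_ndvi(precip, temp, config, ndvi_rng, co2)
        peak = np.full((config.n_lat, config.n_lon), config.peak_month, dtype=int)
        return Scene(config, precip, temp, ndvi, truth, co2, peak)

    nlat, nlon = config.n_lat, config.n_lon
    n_months = config.n_years * 12
    ndvi = np.zeros((n_months, nlat, nlon))
    fields = {k: np.broadcast_to(np.asarray(v), (nlat, nlon))
              for k, v in overrides.items()}
    tr = {k: np.zeros((nlat, nlon)) for k in
          ("obs", "co2", "lu", "cv", "cc", "other")}
    clipped = 0.0
    peak = np.full((nlat, nlon), config.peak_month, dtype=int)
    for i in range(nlat):
        for j in range(nlon):
            kw = {k: (None if (isinstance(v[i, j], float) and np.isnan(v[i, j]))
                      else v[i, j].item()) for k, v in fields.items()}
            # cast year-like overrides back to int
            for key in ("break_year", "peak_month"):
                if key in kw and kw[key] is not None:
                    kw[key] = int(kw[key])
            sub = replace(config, n_lat=1, n_lon=1, **kw)
            nd, t = gen_ndvi(precip[:, i:i + 1, j:j + 1],
                             temp[:, i:i + 1, j:j + 1], sub, ndvi_rng, co2)
            ndvi[:, i, j] = nd[:, 0, 0]
            peak[i, j] = sub.peak_month
            for k in tr:
                tr[k][i, j] = getattr(t, k)[0, 0]
            clipped += t.clipped_fraction
    truth = TruthRecord(obs=tr["obs"], co2=tr["co2"], lu=tr["lu"], cv=tr["cv"],
                        cc=tr["cc"], other=tr["other"],
                        clipped_fraction=clipped / (nlat * nlon))
    return Scene(config, precip, temp, ndvi, truth, co2, peak)
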