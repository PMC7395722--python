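"""Growing-season phenology: from sub-monthly NDVI to annual peak series.

The analysis variable is the annual peak growing-season NDVI (NDVI_max), a
proxy for net primary productivity. For most pixels the peak is taken over
the calendar year; pixels whose climatological growing season peaks in
December have their season wrapped so that January and February of the
following calendar year count toward the previous year's growing season
(Southern-Hemisphere summer seasons straddle the year boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnnualPixelSeries", "monthly_composite", "climatological_peak_month",
           "ndvi_max_annual", "month_index"]

NDVI_MIN, NDVI_MAX = -0.3, 1.0

#: a year with more than this fraction of months missing is flagged invalid
MAX_MISSING_FRACTION = 0.5


@dataclass
class AnnualPixelSeries:
    """Per-pixel annual series aligned to growing-season years."""

    years: np.ndarray
    values: np.ndarray
    peak_month: int = 0  # 1..12; 0 when not applicable (e.g. climate series)
    valid_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    def masked_values(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid_mask] = np.nan
        return out


def month_index(year: int, month: int, start_year: int) -> int:
    """Flat index of (year, month) in a monthly record starting January of
    ``start_year``; month is 1-based."""
    return (year - start_year) * 12 + (month - 1)


def monthly_composite(values, timestamps, valid=None):
    """Aggregate sub-monthly observations to a monthly series by taking the
    maximum of the valid values in each month.

    Parameters
    ----------
    values : sequence of NDVI observations
    timestamps : sequence of (year, month) tuples, sorted
    valid : optional boolean validity flags per observation

    Returns
    -------
    (months, series) where months is a list of (year, month) keys in order
    and series the max-of-valid composite (NaN for months where every
    observation is invalid). Empty input returns two empty arrays.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return [], np.array([])
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    keys = list(timestamps)
    if keys != sorted(keys):
        raise ValueError("timestamps must be sorted")
    months: list[tuple[int, int]] = []
    out: list[float] = []
    for key, v, ok in zip(keys, values, valid):
        if not months or months[-1] != key:
            months.append(key)
            out.append(-np.inf)
        if ok:
            out[-1] = max(out[-1], v)
    series = np.array(out)
    series[~np.isfinite(series)] = np.nan
    return months, series


def climatological_peak_month(monthly: np.ndarray, start_year: int) -> int:
    """Modal calendar month of the annual NDVI maxima over the record.

    Ties break toward the earlier month. Used to decide whether a pixel is
    December-peaking (and hence needs the season-wrap rule).
    """
    monthly = np.asarray(monthly, dtype=float)
    n_years = monthly.size // 12
    if n_years == 0:
        raise ValueError("record shorter than one year")
    counts = np.zeros(12, dtype=int)
    for y in range(n_years):
        block = monthly[y * 12:(y + 1) * 12]
        if np.all(np.isnan(block)):
            continue
        counts[int(np.nanargmax(block))] += 1
    return int(np.argmax(counts)) + 1  # argmax takes the first (earlier) mode


def _season_slice(monthly, start_year, year, peak_month):
    # months belonging to growing-season year `year`
    if peak_month != 12:
        lo = month_index(year, 1, start_year)
        hi = month_index(year, 12, start_year) + 1
    else:
        lo = month_index(year, 12, start_year)
        hi = month_index(year + 1, 2, start_year) + 1
    return monthly[max(lo, 0):min(hi, monthly.size)]


def ndvi_max_annual(monthly, start_year: int, first_year: int, last_year: int,
                    peak_month: int | None = None) -> AnnualPixelSeries:
    """Annual peak growing-season NDVI from a monthly series.

    ``monthly`` starts at January of ``start_year``; output covers
    ``first_year..last_year``. For a December-peaking pixel the season for
    year y is Dec y plus Jan/Feb y+1 (using whatever of those months the
    record contains; the final year falls back to the available months).
    Years with more than half of their season months missing are flagged
    invalid.
    """
    monthly = np.asarray(monthly, dtype=float)
    if peak_month is None:
        peak_month = climatological_peak_month(monthly, start_year)
    years = np.arange(first_year, last_year + 1)
    values = np.full(years.size, np.nan)
    valid = np.zeros(years.size, dtype=bool)
    for i, y in enumerate(years):
        season = _season_slice(monthly, start_year, int(y), peak_month)
        if season.size == 0:
            continue
        n_missing = int(np.isnan(season).sum())
        if n_missing / season.size > MAX_MISSING_FRACTION:
            continue
        if np.all(np.isnan(season)):
            continue
        values[i] = np.nanmax(season)
        valid[i] = True
    return AnnualPixelSeries(years=years, values=values, peak_month=int(peak_month),
                             valid_mask=valid)
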