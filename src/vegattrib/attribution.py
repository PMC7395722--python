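"""Final per-pixel attribution: components, closure, risk classes, summaries.

The observed change in peak NDVI over the analysis window is decomposed into
four drivers — CO2 fertilization, land use (LU), climate variability (CV)
and climate change (CC) — with the unexplained remainder labelled Other
Factors (OF = Obs - (CO2 + LU + CV + CC)). Anthropogenic climate change is
ACC = CO2 + CC. Pixels are classified by desertification risk following the
decision table: a significant negative observed change is Desertification;
otherwise negative ACC and LU together mark "LU and ACC" (highest future
risk), a negative ACC alone marks "ACC", a negative LU alone "LU".
Drylands are the aridity-index band 0.05 <= AI <= 0.65; hyper-arid and
non-dryland pixels are masked, as are changes smaller than the sensor error
(+-0.001 NDVI) or failing field significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AttributionGrid", "decompose", "acc", "dominant_driver",
           "risk_classify", "apply_masks", "area_stats", "RISK_CLASSES"]

EARTH_RADIUS_KM = 6371.0
SENSOR_ERROR = 0.001
AI_HYPER_ARID = 0.05
AI_DRYLAND_MAX = 0.65

RISK_CLASSES = ("Desertification", "LU_and_ACC", "ACC", "LU", "none")

# fixed precedence for exact |delta| ties (measure-zero on real data)
_TIE_ORDER = ("CO2", "LU", "CC", "CV")


@dataclass
class AttributionGrid:
    """Assembled attribution fields on a common (lat, lon) grid."""

    obs: np.ndarray
    obs_p: np.ndarray
    components: dict            # name -> delta grid
    p_values: dict              # name -> p grid
    of: np.ndarray = None
    acc: np.ndarray = None
    dominant: np.ndarray = None
    risk: np.ndarray = None
    masks: dict = field(default_factory=dict)


def decompose(obs, co2, lu, cv, cc) -> np.ndarray:
    """Other-factors residual OF = Obs - (CO2 + LU + CV + CC), elementwise."""
    return (np.asarray(obs, dtype=float)
            - (np.asarray(co2, dtype=float) + np.asarray(lu, dtype=float)
               + np.asarray(cv, dtype=float) + np.asarray(cc, dtype=float)))


def acc(co2, cc) -> np.ndarray:
    """Anthropogenic-climate-change component ACC = CO2 + CC."""
    return np.asarray(co2, dtype=float) + np.asarray(cc, dtype=float)


def dominant_driver(components: dict) -> np.ndarray:
    """Largest-|delta| driver per pixel among CO2, LU, CV, CC.

    Masked (NaN) components do not compete. All-zero or all-masked pixels
    are labelled 'none'; exact ties resolve by the fixed precedence
    CO2 > LU > CC > CV.
    """
    names = list(_TIE_ORDER)
    stack = np.stack([np.abs(np.asarray(components[n], dtype=float)) for n in names])
    shape = stack.shape[1:]
    out = np.full(shape, "none", dtype=object)
    for ix in np.ndindex(shape):
        col = stack[(slice(None), *ix)]
        ok = np.isfinite(col)
        if not ok.any() or np.nanmax(col) == 0.0:
            continue
        col = np.where(ok, col, -np.inf)
        out[ix] = names[int(np.argmax(col))]  # argmax takes first of ties
    return out


def risk_classify(obs_sig, obs_value, acc_value, lu_value) -> np.ndarray:
    """Desertification-risk class per pixel (vectorized decision table).

    Precedence: significant negative observed change -> Desertification;
    else ACC<0 and LU<0 -> LU_and_ACC; else ACC<0 -> ACC; else LU<0 -> LU;
    else none.
    """
    obs_sig = np.asarray(obs_sig, dtype=bool)
    obs_value = np.asarray(obs_value, dtype=float)
    a = np.asarray(acc_value, dtype=float)
    lu = np.asarray(lu_value, dtype=float)
    out = np.full(obs_value.shape, "none", dtype=object)
    out[lu < 0] = "LU"
    out[a < 0] = "ACC"
    out[(a < 0) & (lu < 0)] = "LU_and_ACC"
    out[obs_sig & (obs_value < 0)] = "Desertification"
    return out


def apply_masks(delta, aridity_index, p_field, significant=None,
                alpha: float = 0.10, sensor_err: float = SENSOR_ERROR) -> dict:
    """Build the standard mask set for an attribution field.

    Returns a dict of boolean masks (True = masked out): 'hyper_arid'
    (AI < 0.05), 'non_dryland' (AI > 0.65), 'insignificant' (fails the
    supplied significance mask, or p >= alpha when none is given) and
    'sensor_error' (|delta| <= 0.001). 'any' is their union.
    """
    delta = np.asarray(delta, dtype=float)
    ai = np.asarray(aridity_index, dtype=float)
    p = np.asarray(p_field, dtype=float)
    hyper = ai < AI_HYPER_ARID
    nondry = ai > AI_DRYLAND_MAX
    if significant is None:
        significant = np.isfinite(p) & (p < alpha)
    insig = ~np.asarray(significant, dtype=bool)
    sensor = np.abs(delta) <= sensor_err
    return {
        "hyper_arid": hyper,
        "non_dryland": nondry,
        "insignificant": insig,
        "sensor_error": sensor,
        "any": hyper | nondry | insig | sensor,
    }


def pixel_areas_km2(lat, resolution_deg: float) -> np.ndarray:
    """Spherical-Earth area (km^2) of each latitude band's pixels.

    ``lat`` are cell-center latitudes; each pixel spans ``resolution_deg``
    in both directions.
    """
    lat = np.asarray(lat, dtype=float)
    half = np.deg2rad(resolution_deg) / 2.0
    phi = np.deg2rad(lat)
    dlon = np.deg2rad(resolution_deg)
    return (EARTH_RADIUS_KM**2) * dlon * (np.sin(phi + half) - np.sin(phi - half))


def area_stats(values, lat, resolution_deg: float, mask=None):
    """Area-weighted summary of a gridded field.

    Weights are proportional to cos(latitude) times the pixel angular
    area (i.e. the true spherical pixel area). Returns a dict with the
    weighted mean and SD, the total unmasked area (km^2), and — for each
    value when ``values`` is categorical — area fractions in percent.
    ``mask`` is True where pixels are excluded.
    """
    values = np.asarray(values)
    lat = np.asarray(lat, dtype=float)
    band = pixel_areas_km2(lat, resolution_deg)
    areas = np.broadcast_to(band[:, None], values.shape).copy()
    keep = np.ones(values.shape, dtype=bool)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    if values.dtype.kind in "fc":
        keep &= np.isfinite(values.astype(float))
    w = areas * keep
    total = float(w.sum())
    out = {"area_km2": total}
    if values.dtype.kind in "fc":
        v = values.astype(float)
        mean = float((w * np.where(keep, v, 0.0)).sum() / total) if total > 0 else np.nan
        var = float((w * np.where(keep, (v - mean)**2, 0.0)).sum() / total) if total > 0 else np.nan
        out["mean"] = mean
        out["sd"] = float(np.sqrt(var)) if np.isfinite(var) else np.nan
    else:
        fractions = {}
        for label in np.unique(values[keep]) if total > 0 else []:
            sel = keep & (values == label)
            fractions[str(label)] = 100.0 * float(areas[sel].sum()) / total
        out["fractions_pct"] = fractions
    return out
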