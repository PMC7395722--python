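# Methods

This note documents the model choices, parameters, numerical decisions and
known limitations of the attribution pipeline. It is the design record; all
empirical numbers quoted are the ones computed by the test suite and
`scripts/acceptance.py`.

## Change metric and trend machinery

Every driver is expressed as a change in annual peak NDVI over the analysis
window, Δ = slope × window factor. The window factor defaults to
`end_year − start_year` (33 for 1982–2015), which makes Δ exactly the
difference of the fitted expected values at the window ends under a linear
fit; a `count_years=True` toggle gives the record-length convention (34)
instead. Slopes are Theil–Sen (median of pairwise slopes; intercept is the
median of `y − slope·x`, matching `scipy.stats.theilslopes(method="joint")`),
significance is Spearman's ρ against year. For n ≤ 8 the Spearman p-value
is computed by exact enumeration of the permutation null (ties through
average ranks); above that the t approximation is used, which is accurate
at the 30+ year series lengths the pipeline operates on. A series with all
values tied returns ρ = 0, p = 1. Field significance across pixels uses
Benjamini–Hochberg at α_FDR = 0.10, with missing pixels excluded from the
test count.

## CO₂ fertilization adjustment

The RuBP-regeneration-limited response ratio (baseline c_a0 = 339 µmol/mol
at 1980, Γ* = 40 µmol/mol) is applied to every monthly NDVI value before
phenology, dividing the observed series by the pathway-weighted ratio. The
ratio model deliberately excludes Rubisco-limited kinetics and indirect
effects (stomatal water savings, growing-season extension); it is a
conservative estimate of the fertilization signal. Negative NDVI values
pass through the division unchanged — they occur over bare soil and are
removed by the aridity masks anyway. The default CO₂ history interpolates
piecewise-linearly through {1960: 317, 1980: 339, 2000: 369, 2015: 399}
µmol/mol and is user-overridable; only the 1980 anchor is methodologically
pinned (it defines the baseline).

## Phenology

Annual NDVI_max is the maximum over the pixel's growing season. The
climatological peak month is the modal month of the annual maxima over the
record, ties broken toward the earlier month. Pixels peaking in December
wrap their season: year y takes max(Dec y, Jan y+1, Feb y+1), with the
final year using whatever months the record contains. Years with more than
half their season months missing are invalid. Sub-monthly composites take
the maximum of valid observations per month.

## Vegetation–climate relationship and land use

The VCR is an OLS regression of adjusted peak NDVI on precipitation summed
and temperature averaged over per-pixel windows, searched exhaustively over
1–12 month accumulations and 0–3 month offsets ending at the peak month.
The search is vectorized through the closed-form two-predictor R²
(correlation algebra), so all ~2300 window pairings are scored with a few
matrix products and only the winner is refitted.

Two guards temper the exhaustive search:

- **Temperature inclusion.** Maximizing R² over 48 temperature windows
  will fit pure noise (in early experiments the temperature coefficient
  inflated several-fold on null pixels, biasing the climate-change
  component). Temperature is therefore retained only when the best joint
  model beats the best precipitation-only model in a partial F-test
  Bonferroni-corrected for the number of searched temperature windows
  (α = 0.05). A genuine temperature signal of the size used in the
  validation scenes passes this comfortably; noise almost never does.
- **Collinearity.** If the winning accumulated series have
  |corr| > 0.95, temperature is dropped (precipitation is the primary
  dryland driver).

Structural breaks: the candidate year maximizes the |CUSUM| of the demeaned
residuals, constrained to leave ≥5 years per segment, and is confirmed by a
Chow F-test of the residual-versus-year regression, Bonferroni-corrected
for the number of scanned candidate positions (the scan selects the most
extreme candidate, so the uncorrected test would be badly anticonservative
— measured false-positive rate ~1–3 % at nominal 5 % after correction,
~97 % of 0.05–0.1 NDVI steps located within ±1 year at noise 0.005–0.02).
A confirmed break is classified as a `vcr_break` when the VCR regression
itself breaks (segment-intercept dummy significant), in which case the VCR
is refitted with separate intercepts; otherwise it is a `residual_break`.
One break maximum per pixel — a 34-year record cannot support more.

The LU component is the OLS trend of the VCR residuals: without a break,
slope × window factor with the slope's t-test p; with a break, a segmented
fit (separate intercepts, common slope unless a Chow test rejects slope
equality) evaluated as fitted(end) − fitted(start), so step and trend are
both captured, with the regression-vs-constant F-test p.

## Climate change vs. variability

The accumulated climatology is built from 1963 onward (the record starts
in 1962; the first year's window may be incomplete) on the VCR's optimal
windows, smoothed with a 20-year leading-edge mean (only complete windows,
which the record start guarantees for 1982+). β is the Theil–Sen slope of
the smoothed series within the analysis window; the detrended climatology
is x_n − β(n − n₀) anchored at n₀ = 1982, so CC anomalies are zero at the
analysis start. Precipitation and temperature are detrended independently.
NDVI_CL and NDVI_CV are computed by evaluating the VCR's *climate
coefficients only* on the observed and detrended climatologies — segment
(land-use step) intercepts are excluded so a break never leaks into the
climate components. Standardized anomaly series (observed, CC, CV) use the
observed mean and SD of the accumulated series.

β estimated from a 20-year moving mean of dryland rainfall is noisy per
pixel (the smoothed series is heavily autocorrelated; relative errors of
tens of percent are normal). This noise swaps amplitude between CV and CC
at single pixels but cancels in their sum and averages out across a scene;
scene-level CC/CV estimates are unbiased. Per-pixel CC should be read with
that uncertainty in mind — as in the real-data application, where the
global CC component is an order of magnitude smaller than its spatial
spread.

## Ensemble and significance protocols

Matched members (every precipitation × temperature dataset pairing) are run
per pathway. Pathway merge: component Δs are the per-pixel
(1−f_C4)/f_C4-weighted mean of the matched C3 and C4 runs; p-values merge
by weighted Stouffer with z = sign(Δ) · Φ⁻¹(1 − p/2). A member with p = 1
(e.g. the CO₂ test of a C4 run, which has no fertilization signal by
construction) maps to z = 0 and contributes no evidence either way; p-values
at machine bounds are clipped. Across the 12 members, Δs combine by
unweighted mean (median available), LU/CV/CC p-values by Fisher's method,
and the CO₂ p-value — which does not depend on the climate dataset — is the
members' common Spearman p. The agreement protocol (strictly >50 %
significant, strictly >80 % directional agreement among the significant)
and the breakpoint consensus rule (>50 % significant breaks, ≥80 % within
a 3-year window, consensus year = median of the in-window years) are
applied per pixel; pixels with fewer than 6 surviving members are masked.

## Attribution assembly

OF = Obs − (CO₂ + LU + CV + CC); ACC = CO₂ + CC. Dominant driver is the
largest |Δ|, with masked components excluded from the competition and exact
ties resolved CO₂ > LU > CC > CV (measure zero in practice). Risk classes,
in precedence order: significant negative Obs → Desertification; ACC < 0
and LU < 0 → "LU and ACC"; ACC < 0 → "ACC"; LU < 0 → "LU"; else none.
Masks: AI < 0.05 (hyper-arid), AI > 0.65 (non-dryland), failed field
significance, |Δ| ≤ 0.001 (sensor error). Area weighting uses exact
spherical pixel areas (R = 6371 km); the band-area formula reproduces the
sphere's surface to 0.1 %.

## Synthetic scenes and what they do (and do not) show

The generator draws monthly rainfall from a gamma distribution (default
shape 2 → monthly CV ≈ 0.7, dryland-typical) with an optional linear trend
in the mean, Gaussian temperature (default monthly sd 1.0 °C — real
interannual variability; importantly, variability must dominate the trend
within the record for residual-trend attribution to be identifiable at
all), and builds each annual peak as
(intercept + c_P·P_acc + c_T·T_acc + LU trend + step + noise) ×
((1−f_C4)·GPP_rel + f_C4), spread over months by a fixed seasonal shape
peaking in the configured month and clipped to [−0.3, 1] (a warning fires
if clipping touches >5 % of peaks). The truth record stores each forcing's
isolated Theil–Sen Δ — the same convention the pipeline reports — computed
from the realized noise-free series, so recovery comparisons are
like-for-like. Everything is bit-reproducible from the seed.

The standard validation scene (16×16, 1962–2015) activates all forcings in
known spatial blocks: gradual greening (+0.002/yr) and degradation
(−0.001/yr), an abrupt −0.08 step in 2000, a C4 fraction ramping 0→0.6,
scene-wide wetting (0.25 mm month⁻¹ yr⁻¹) and warming (0.02 °C yr⁻¹)
with c_P = 0.0015 NDVI/mm and c_T = −0.03 NDVI/°C, and NDVI noise 0.01.
Forcing magnitudes were chosen once so each signal is detectable by
construction at realistic noise (a recovery test of an undetectable signal
validates nothing) and the scene greens on net, like the real dryland
domain. The pseudo-ensemble emulates dataset disagreement with systematic
biases (precipitation ×0.95–1.08, temperature ±0.3 °C) plus observational
noise per member.

Not emulated: sensor/orbit drift, cloud and snow contamination, spatial
autocorrelation of NDVI noise, autocorrelated (e.g. ENSO-like) climate
variability, and nonlinear vegetation–climate response. Passing recovery
here shows the chain of estimators is correct and calibrated under the
model's own assumptions — not that those assumptions hold for any real
sensor record.

## Known limitations

- **Per-pixel closure is inexact by construction.** The components mix
  estimators — Theil–Sen deltas (Obs, CO₂, CV, CC), OLS residual trends
  (LU), segmented endpoints at breaks — and Theil–Sen is not additive:
  TS(x+e) − TS(x) − OLS(e) has sd ≈ 0.006 NDVI at noise 0.01 under
  dryland climate variability, and the TS delta of a pure step exceeds
  the step itself by ~10–30 %. OF therefore carries a per-pixel residual
  of that order even on model-consistent scenes (it vanishes on
  noise-free, break-free scenes, where all estimators are
  linear-equivariant). Aggregate closure is much tighter than per-pixel
  closure; both are reported by the acceptance script.
- RESTREND-family attribution cannot fully separate a LU time-trend from
  a climate trend when the climate series' trend rivals its variability;
  the temperature-inclusion guard and realistic variability keep the
  resulting bias small but not zero.
- The breakpoint machinery assumes at most one break and annual
  resolution; slow multi-decade regime shifts are absorbed into trends.
- Regridding between native dataset grids is out of scope: inputs must be
  co-registered. GeoTIFF export is not provided; NetCDF (scipy backend,
  NetCDF3 classic) and CSV are the interchange formats.
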