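# Methods

`aonrvi` implements a transect-based workflow for deciding in-season nitrogen
(N) rates in corn from 4-band (Blue/Green/Red/NIR) satellite reflectance. The
workflow answers three questions about an on-farm N-rate strip trial: how well
do vegetation indices (VIs) track final grain yield at each image timing; can
VI–N dose-response curves stand in for yield–N curves; and how close is the
VI-derived agronomic optimum N rate (AONRvi) to the yield-derived one (AONRy).
Because raw trial data of this kind are rarely shareable, the package ships a
first-class synthetic trial generator with known ground truth, and every
downstream stage is tested against that truth.

## The experimental unit and the study design

A *transect* is a set of adjacent subplots on uniform soil that together cover
the full ladder of N-rate treatments; it is the unit on which dose-response
curves are fitted. The default study design is three trials of 8 transects
each: a strip-till field following soybean ("ST-S", high residue cover, 5
distinct rates 44–289 kg N ha⁻¹ at 55 m × 9.14 m subplots) and two
conventionally tilled fields ("CT-C" after corn, "CT-S" after soybean; 61 m ×
18.29 m subplots) whose lowest treatment (50% of the farmer's normal rate) is
applied twice, so they span 4 distinct rates with 5 subplots per transect.
Buffers of 1.5 m between adjacent subplots and 15 m between consecutive
subplots avoid cross-treatment border effects. Seven image timings cover
growth stages V7 through R6; timings 1–3 (V7–V16) are the vegetative window
in which in-season N decisions are possible.

This design enumerates to 3 × 7 × 16 = 336 VI–yield regressions (144
vegetative + 192 reproductive) and 24 × 3 × 16 = 1,152 VI–N response curves
(384 per field, 72 per VI), and the batteries always emit exactly these
counts, using flagged placeholder rows for degenerate cells rather than
dropping them.

## The synthetic trial generator

**Ground truth.** Each transect draws a true AONR from a normal distribution
(default mean 185, sd 25 kg N ha⁻¹) truncated to (0, max tested rate], and a
plateau yield from N(13.0, 0.8) Mg ha⁻¹. Expected subplot yield follows a
rise-then-plateau family — quadratic-plateau by default (smooth vertex at the
AONR) or linear-plateau — anchored at 55% of the plateau yield at N = 0.
These defaults are plausible for rain-fed Midwest corn at the trials' rate
ladders; they were chosen once as the study conditions, not tuned.

**Scenes.** Reflectance is rendered by per-pixel linear spectral mixing on a
3-m grid:

    ρ = f · canopy + (1 − f) · [r · residue + (1 − r) · soil] + ε

where `f` is the subplot's canopy cover fraction at the timing, `r` the
trial's residue cover (0.6 / 0.25 / 0.10 for ST-S / CT-C / CT-S), and
ε ~ N(0, 0.01) per band. The endmember spectra shipped in the default config
are synthetic (plausible green canopy / bare soil / dry residue values), not
instrument measurements. Scenes are stored in the scaled-integer convention
(reflectance × 10,000, unsigned 16-bit); the rounding this implies is a real
~10⁻⁴-reflectance noise source and can be switched off
(`quantize_scenes=False`) for exact-recovery studies.

**Canopy model.** Cover grows logistically in timing index (rate 1.4,
midpoint 1.8 — about 25% cover at V7–V8 rising to ~95% by R1) and is scaled
by an N-sufficiency factor `min(1, N/AONR)^γ` with γ = 0.5 (diminishing
returns). No canopy-growth model is prescribed by the analysis itself; this
one reproduces the qualitative patterns that matter — VI increases with N and
saturates at the transect optimum, early timings carry more soil/residue
signal, high-residue backgrounds compress the VI–N contrast. A second mode
(`canopy_response="plateau"`) makes cover follow the *same* plateau family as
yield, normalized to [0.4, 1]; with that mode, any VI that is affine in band
reflectance (EXG, DVI, GREEN, EXR) has an N-response in exactly the yield
family with the same join point, which is what end-to-end recovery checks
require.

**Yield monitor.** One serpentine combine pass per transect, with readings
spaced so each subplot gets `points_per_subplot` (default 20) observations
plus buffer-gap readings that fall outside every zone. Wet yield is derived
by inverting the moisture standardization, so standardizing recovers the
noisy per-point yield exactly. A configurable fraction of points (default 5%)
carries one injected, labeled artifact: out-of-range moisture (7% / 36%),
out-of-range speed (0.65 / 9.0 mph), a >15% speed spike, a heading spike
(+75°), or a gross yield outlier (×2.5). After any speed artifact the stream
ramps back to its baseline at ≤13% per reading so that only injected points
violate the jump rule; baseline speeds follow a bounded random walk with
steps far below 15%. Truth labels ride along in the output (`artifact`,
`true_subplot`) so filter recall is measurable.

**Determinism.** Truth, scene noise, harvest stream, and artifact injection
draw from separate `SeedSequence([seed, trial_index, stream])` generators, so
identical configurations reproduce byte-identical outputs regardless of call
order, and artifact injection never perturbs field truth.

**What the generator does not emulate** — and hence what green tests do *not*
establish about real data: spatial autocorrelation of soil and yield within
transects, weather-driven temporal variation between acquisitions,
atmospheric/BRDF residuals, canopy shadowing and row-direction effects,
yield-monitor flow-delay and swath-overlap errors, and georeferencing error.
Real-data retention and agreement numbers will be worse than the synthetic
ones; the synthetic study validates the *machinery* (formulas, screens,
optimizers, bookkeeping), not field-scale performance.

## Vegetation indices

Sixteen indices, eight visible-band (EXG, EXR, VDVI, PPRB, VARI, VIG, DVI,
GREEN) and eight NIR-based (NDVI, GNDVI, OSAVI, SAVI with L = 0.5, CVI, RDVI,
GARI, EVI2). Two naming quirks are kept deliberately: "DVI" here is the
green–red difference G − R (not the usual NIR − R difference), and GARI is
implemented as the standard normalized ratio (NIR − X)/(NIR + X) with
X = G − 1.7(B − R) — the literal left-to-right reading of its commonly
printed formula is a typesetting artifact. Zero denominators produce NaN
(counted), never ±∞, so zonal means and regressions stay finite. Zonal means
use the pixel-center rule on half-open pixels; subplot zones are pixel-index
sets, so CRS handling is limited to writing a valid affine transform into the
GeoTIFF tags.

## Yield cleaning

Flag order: outside study area → abnormal heading → moisture outside
[10%, 33%] → speed outside [0.7, 8.2] mph → speed change >15% from the
previous reading of the acquisition sequence. All applicable flags are
recorded; retained yields are standardized to 150 g kg⁻¹ moisture
(`adjusted = wet · (1 − m/100)/0.85`), then values beyond ±3 sample standard
deviations from their treatment-within-field mean are removed in a single
pass (mean and SD computed before removal). "Abnormal heading" has no
standard definition; it is implemented as more than 30° (configurable) from
the pass's circular median heading. The speed-jump rule applies only between
consecutive readings (sequence difference of one), so the filter is
idempotent on its own retained output. The ±3 SD scope (treatment within
field vs within transect) is a switch; within-field is the default.

## Regression screening

Per (field × timing × VI): ordinary least squares of subplot mean yield on
subplot mean VI, R² = 1 − RSS/TSS, RMSE with the 1/n convention, and
nRMSE = RMSE/(y_max − y_min) so sites with different yield ranges compare.
Significance is the two-sided slope t-test at p < 0.10 (identical to the
model F-test for simple regression). No multiple-testing correction is
applied — the battery is a descriptive screen, not joint inference. Each
duplicated 50%FNR subplot enters as its own observation.

## Plateau fitting, screening, selection

Families: linear-plateau `a + b·min(x, x₀)` and the smooth-vertex
quadratic-plateau `a + bx + cx²` capped at `x₀ = −b/(2c)` with plateau value
`a − b²/(4c)`. For a fixed join both are linear in their remaining
coefficients, so fitting profiles the join: 21 uniform candidates plus five
per inter-observation segment (narrow segments can hide basins), conditional
OLS at each, bounded Brent refinement of every local basin and every segment,
then a bounded `least_squares` polish. On 5-point transect data this provably
tracks the exhaustive profile to ≤10⁻⁸ relative RSS — and can beat a naive
dense-grid oracle, because the profile's minimum often sits exactly on a data
breakpoint that interior-point searches cannot touch. The linear-plateau join
is constrained to the tested range; the quadratic vertex may fall beyond it
(that is what the exceeds-maximum discard rule is for).

Screening, in order: convergence; R² > 0.50 (strict); plausibility — positive
slope for the linear-plateau, concave-down (c < 0) for the quadratic. Among
survivors the lower AIC wins, with AIC = n·ln(RSS/n) + 2(p + 1) and p = 3 for
both families, so at equal n selection reduces to RSS. Ties (|ΔAIC| < 10⁻⁹,
including double-perfect fits) prefer the quadratic-plateau. RSS below
10⁻¹²·TSS is treated as an exact zero so floating-point residue cannot break
the tie rule. The selected join is the candidate AONR; a join strictly above
the maximum tested rate discards the curve (a join *at* the maximum is kept —
it is observed, not extrapolated). The same screen-and-select procedure
produces AONRy from the yield–N data; transects whose yield curve fails
screening contribute no comparison pairs.

A structural caveat the tests respect: with the duplicated-lowest-rate design
(4 distinct rates), a true optimum at or below the second distinct rate
leaves at most one distinct observation on the rising limb, and the join is
then mathematically under-identified — many exact fits share the data but
differ in join. Exact-recovery checks therefore restrict to transects whose
true join clears the second distinct rate by ≥5 kg ha⁻¹.

## Agreement metrics

Each retained VI–N curve contributes one pair against its transect's AONRy:
signed percent difference (AONRvi − AONRy)/AONRy × 100 (negative =
underestimation), squared Pearson correlation over pairs, RMSE and MAE in
kg N ha⁻¹. Group summaries (by field, timing, VI, VI group) are unweighted
over their pairs; undefined correlations (n < 2 or zero variance) are
reported as missing, never zero.

## Problem sizes and numerical choices

The shipped studies use: the full 3 × 8-transect design with 20 yield points
per subplot for enumeration and retention; 200 random 5-point datasets for
oracle equivalence; 500 synthetic transects for parameter recovery (5%-of-
range noise, and noise-free); 10,000 null regressions at n = 20 for type-I
calibration; ~1,200 labeled yield points at 10% artifact rate for cleaning
recall. Scene grids are ~30 × 120 pixels per trial. Key tolerances:
optimizer join accuracy ≤0.5 kg ha⁻¹ at zero noise; profile/oracle agreement
10⁻⁸ relative RSS; AIC tie 10⁻⁹; perfect-fit epsilon 10⁻¹²·TSS; pixel
membership by center point on half-open pixels.

## Known limitations

Red-edge and SWIR indices are out of scope (the 4-band sensor convention has
neither). No economic optimum (price-ratio) analysis, no confidence
intervals on AONR (a bootstrap would slot in at `fit_and_screen`), no
flow-delay or swath-overlap yield corrections, no real-CRS reprojection.
Retention percentages on synthetic data (~70–75% under default noise) are
far above what field data yield, because the generator's response curves are
genuinely plateau-shaped at every transect; on real trials most curves fail
the R² screen. The generator's speed ramp-back guarantees zero false
positives for the jump rule on clean points, which real streams do not.
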