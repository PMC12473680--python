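# Methods

This note documents the models, numerical choices and known limitations of
`phenofuse`, in the spirit of a statistical package's model documentation.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem

Optical NDVI monitoring of cropland in persistently cloudy regions leaves
each sensor with a sparse, irregular set of usable observations per season.
The pipeline reconstructs a continuous seasonal NDVI trajectory per pixel
from whatever observations survive cloud masking, places three sensors with
different resolutions and revisit rates on one spatio-temporal grid, and
uses the reconstructed weekly series to classify five land-cover classes:
soybean, grain crops (wheat/oat/barley pooled), buckwheat, perennial
grasses, and fallow land.  The growing season is fixed to days of year
121–296 (early May to late October; only spring crops are grown in the
target region).

## Cloud masking

* Sentinel-2 L2A: a pixel is unusable iff its SCL code is in
  {0 no-data, 1 saturated/defective, 3 cloud shadow, 8 medium cloud,
  9 high cloud, 10 haze/cirrus, 11 snow}.  All other codes — including
  2 (dark-area pixels), which the rule set leaves unlisted — are treated
  as valid; treating code 2 as valid is an interpretation made here and
  flagged as such.
* Landsat Collection 2: a pixel is usable iff `QA_PIXEL` equals exactly
  21 824 (clear land); everything else is masked.
* Meteor-M: delivered as daily NDVI composites without a quality layer;
  its masks are all-true except for explicit no-data values.

Masked pixels propagate as missing values (never zeros) so the curve fit
sees only genuine observations.  Scenes are tallied into masked-fraction
bins <5 %, 5–20 %, 20–50 %, >50 %, half-open on the left (exactly 5 %
falls in the second bin); "cloud-free" means the first bin.

## Harmonic gap filling

The seasonal model per pixel is the two-term Fourier series
`f(x) = a0 + a1 cos(wx) + b1 sin(wx) + a2 cos(2wx) + b2 sin(2wx)` with
x = day of year.  Numerical choices:

* **Variable projection.**  For fixed `w` the model is linear in the five
  coefficients, so `w` is profiled: coefficients come from an exact linear
  least-squares solve and `w` from a bounded scalar search of the profiled
  residual sum of squares.  This is the same objective as a joint 6-parameter
  nonlinear fit but deterministic, free of convergence failures, and
  vectorisable over ~10⁵ pixels.
* **Frequency prior and bounds.**  The search grid spans
  `w ∈ [2π/800, 2π/120]` per day and always contains the canonical seasonal
  start value `2π/368` (one cycle over roughly twice the season).  Exact
  ties — e.g. a constant series, which any `w` fits perfectly — resolve to
  the canonical value.  The scalar path refines with bounded Brent iteration
  (`xatol` 1e-12); the raster path uses a 22-point grid plus one parabolic
  refinement step per pixel.
* **Minimum observations.**  `min_obs = 8` (six parameters plus two).
  Scalar fits below the threshold raise an error carrying the pixel
  coordinate; raster fits flag the pixel as unfittable (NaN) and report the
  exclusion count in the stage diagnostics.
* **Reconstruction.**  The fitted curve is evaluated at all 176 integer days
  of DOY 121–296 and clipped to the NDVI domain [−1, 1].
* **Weekly composites.**  26 anchors at DOY 121 + 7k, k = 0…25; each anchor
  takes the mean (max available as an option) of the daily values in
  [anchor, anchor + 6], truncated at the season end.

Meteor-M series are never harmonic-fitted (the delivered product is already
a gap-filled composite built by a provider-side local-regression chain):
weekly anchors take the mean of valid days in their window; interior empty
windows are linearly interpolated between neighbouring anchors and
leading/trailing empty anchors take the nearest valid anchor value, since
the delivery window (DOY 122–269) does not span the full season.

## Harmonization

A regular geographic grid with pixel size `resolution_m / 111 000` degrees
(≈ 0.00054° at 60 m) is the common target.  Latitude convergence is
deliberately ignored — pixel size is constant in degrees, matching the
equatorial 1° ≈ 111 km conversion — and documented as a known
approximation.  Weekly layers (already gap-filled, in that order) are
resampled by bilinear interpolation at target cell centers with a
conservative missing-data rule: if any of the four source neighbours is
missing, the output cell is missing, rather than re-normalising weights.
This avoids silently blending values across cloud edges at the cost of
slightly wider missing margins.  Conventions: row-major, north-up, 0-based
indices, cell-center registration, (longitude, latitude) coordinate order.

## Phenology indicators

* Per field: the unweighted per-week mean over the field's cells, then
  NDVImax = max over the weekly grid and DOYmax = its anchor (ties take the
  earliest anchor, i.e. DOYmax has 7-day resolution on the weekly grid).
* Two-maximum analysis: classes with an early and a late peak (mown
  grasses, buckwheat re-sown mid-season) are summarised by the maxima on
  either side of a split day, default DOY 210 (late July), which separates
  the observed late-June first maxima from August–September second maxima.
  The split is configurable.
* Class summaries report mean ± half-width of a 95 % t-interval of the mean
  and the coefficient of variation (sd/mean·100).  The interval choice is a
  documented assumption; published tables of this form do not always define
  their "±" and no attempt is made to match such half-widths numerically.
* Year comparisons: one-way ANOVA (F test) plus Tukey HSD pairwise p-values
  from the studentized-range distribution (Tukey–Kramer under unequal n),
  via `scipy.stats`.  Degenerate input (zero variance in every group) is
  flagged: F = 0 / p = 1 when all values coincide, F = ∞ / p = 0 when group
  means differ with zero spread.

## Classification and evaluation

* **Samples and features.**  One sample per 60 m cell inside a labeled
  field; features are the cell's 26 weekly NDVI values per sensor
  (26 single-sensor, 78 three-sensor).  Cells missing any sensor-week value
  are excluded from all feature sets so every comparison uses the same
  cells.
* **IQR filter.**  Per class and per feature on the training partition
  only: bounds [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by linear
  interpolation of order statistics ("type 7"); a row is removed when any
  feature leaves its class bounds.  Classes with fewer than four training
  rows are passed through with a warning.
* **Grouped split.**  Whole fields are assigned to one side.  Within each
  class the shuffled fields fill the test side until its row count reaches
  the target fraction (default 50 %), skipping fields that would overshoot
  more than they help; this keeps per-class area ratios close to the
  configured ones by construction rather than by a repair pass.
* **Forest.**  50 bagged axis-aligned decision trees (scikit-learn
  `RandomForestClassifier` defaults otherwise), seeded explicitly.
* **Metrics.**  Confusion matrix with rows = actual, columns = predicted in
  the canonical class order (soybean, grain crops, buckwheat, perennial
  grasses, fallow); OA = trace/total in percent; per-class
  F1 = TP/(TP + (FP + FN)/2); F1mean unweighted over classes present in
  the evaluation (absent classes excluded with a warning).  Reports round
  OA to whole percent and F1 to two decimals.
* **Cross-validation.**  scikit-learn `StratifiedGroupKFold` (k = 3,
  shuffled, seeded) with fields as groups; per-fold reports plus a pooled
  report from the summed confusion matrix.
* **Crop maps.**  Field-level maps assign each field the modal predicted
  class of its cells; ties break by total predicted-probability mass, then
  canonical class order.

## The synthetic landscape generator

The generator defines the study conditions for all closed-loop testing.

* **Geometry.**  A rectangular block landscape: row strips of 4–10 cells
  (60 m) height split into fields of 4–10 cells width with a 1-cell gap,
  ≈ 200 fields on the default 100×100-cell domain.  Classes are assigned by
  a greedy area-quota rule tracking the pooled three-season area shares
  (soybean 56.5 %, fallow 19.4 %, grain crops 12.8 %, perennial grasses
  7.3 %, buckwheat 3.9 %).
* **Truth curves.**  Each field draws peak value and peak day from its
  class distribution (truncated normals, ±4 sd).  Defaults follow the 20 m
  sensor's published field summaries: soybean 0.88 ± 4.9 % at DOY 221,
  grain crops 0.77 ± 5.1 % at DOY 192 (timing CV 14.8 %), fallow
  0.84 ± 5.8 % at DOY 191; perennial grasses are bimodal (0.81 at DOY 174,
  0.78 at DOY 265), and buckwheat uses the late-sown bimodal pattern
  (small early rise near DOY 165, main peak 0.80 at DOY 243) so the
  two-maximum analysis is exercised by default.
* **Curve families.**  The default unimodal family is built in the same
  truncated Fourier basis as the fitting model (frequency 2π/368, with a
  second-harmonic "sharpness" term; sharpness must stay above −0.25 for the
  peak to remain a maximum), so the noiseless closed loop recovers the
  truth exactly and simulator error is not confounded with fitter error.
  Bimodal classes use a two-Gaussian mixture and are therefore deliberately
  out-of-basis; a double-logistic family is available for robustness
  checks.
* **Sensors.**  20 m sensor: one scene every 3 days with ±1 day jitter
  (~59/season), reflectance pair + SCL grid, no bias.  30 m sensor:
  11/12-day alternating cadence (~16/season), reflectance pair + QA grid,
  +0.03 NDVI bias.  60 m sensor: daily NDVI composites over DOY 122–269,
  −0.06 NDVI bias and a 15-day-earlier season, mirroring the reported
  inter-sensor offsets (maxima lower by ~0.05–0.08, earlier by 10–20 days).
  Observation noise 0.02 NDVI (0.015 for the smoother daily composites);
  within-field spatial spread 0.02 NDVI sd (a free parameter of the
  simulator — the published tables characterise field-to-field, not
  within-field, variance).
* **Clouds.**  Each scene draws a masked-fraction bin from the published
  2022-season scene tallies (20 m sensor: 8/61, 5/61, 11/61, 37/61), then a
  fraction uniform within the bin; the cloud is a spatially coherent blob
  (jittered distance transform from 1–4 random seeds, thresholded at the
  exact pixel count) rather than i.i.d. pixels, because real clouds are
  contiguous.  Cloudy pixels are overwritten with cloud-like values
  (NDVI ≈ 0.05) so an un-applied mask is detectable, and encoded in the
  quality grids so the masking stage is exercised end-to-end.
* **Determinism.**  All randomness flows from `numpy` SeedSequences derived
  from the landscape seed and a stable per-sensor key; identical config and
  seed give bit-identical stacks.

### What the generator does *not* emulate

Radiative transfer, atmospheric correction residuals, BRDF and view-angle
effects, topography, mixed pixels at field boundaries beyond what grid
resolution imposes, sensor-specific spectral response differences beyond an
additive NDVI bias, the provider-side smoothing of the daily-composite
product, and spatially correlated noise within a scene.  Passing closed-loop
tests therefore demonstrates the pipeline's internal consistency and its
statistical behaviour under calibrated conditions — not performance on real
imagery.

## Problem sizes used in testing

The default landscape is 100×100 target cells (≈ 6×6 km) with ~200 fields —
a deliberately compact stand-in for a district-scale study (the emulated
study pooled 421–996 fields per season over ~36 000 ha).  The end-to-end
checks run one full cross-validated experiment on this landscape (seed 42)
and a ten-seed multi- vs single-sensor comparison using grouped 50/50
splits; the harmonic closed loop uses 15-observation series with 100 noise
replicates.  These sizes are the package's chosen trade-off between
statistical resolution and a test suite that runs in minutes.

## Known limitations

* Constant-in-degrees pixels distort metric cell size away from the
  equator; at ~48° N a "60 m" cell is ~40 m east–west.
* DOYmax from the weekly grid has 7-day resolution; daily-resolution maxima
  are available from the reconstructed daily series where a harmonic fit
  exists (not for the daily-composite sensor).
* The conservative bilinear missing rule erodes one source-pixel margin
  around clouds and domain edges.
* The IQR "any feature out of bounds" rule is aggressive in 78 dimensions
  and can remove a substantial share of training rows; it follows the
  outlier-removal formulation rather than per-feature capping.
* With the default calibration the single-sensor inputs already classify
  the synthetic landscape near ceiling, so the multi-sensor gain observed
  on real, cloud-limited data manifests here only as parity (the tests
  assert non-inferiority within 2 points, not superiority).
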