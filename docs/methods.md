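# Methods

## Problem

High-throughput phenotyping platforms image whole plants with fixed camera
settings, so the per-leaf resolution is poor: blur mixes the colors of
neighboring pixels, and because the red, green and blue sensor bands are
blurred to different degrees — and leak into one another — thin green
leaves acquire yellow fringes at their edges. A naive color classification
then reports double-digit "senescence" on plants that are entirely green,
and the onset of real senescence cannot be timed. `leafsen` implements a
correction for this channel-coupled color distortion, followed by a zonal
color classification of senescence, trajectory/onset statistics, and a
correlation against manual 1–10 senescence scores.

## Degradation model and correction

The observed image is modeled as X = G·D + N: every output channel of X is
a linear combination of L_d × L_d neighborhoods of *all* channels of the
true image G (no shared PSF across bands, no channel independence), plus
noise N. Rather than estimating and inverting D — impossible here because
the distortion is inhomogeneous across channels and asymmetric — the
*correction* operator is estimated directly. Arrange X into a design
matrix of shape S_i × M (S_i pixels; M = L²·N_c; row i is pixel i's full
L × L × N_c neighborhood, replicate-padded, in channel-major order) and
the reference G into an S_i × N_c target. The correction matrix

    C = argmin ‖G − XC‖² + ridge·‖C‖²,

solved by the normal equations (or the SVD pseudoinverse when ridge = 0),
restores any image under the same camera settings via R = XC. The fit is
needed once per experiment.

Key numerical choices:

- **Kernel size L = 5** (M = 75 for RGB). Chromatic fringes span a few
  pixels; 5 covers them while the normal equations stay tiny (75×75).
- **Ridge default `"auto"` = 1e-6 · trace(XᵗX)/M.** A plain inverse fails
  on rank-deficient content (flat backgrounds); this scale-aware ridge
  stabilizes such fits without measurably biasing well-conditioned ones.
  With ridge 0 a rank-deficient system raises an error instead of
  silently regularizing.
- **Noise is absorbed by the residual.** Least squares is the
  maximum-likelihood estimator under Gaussian noise; no separate noise
  model is fitted.
- **Clipping to [0, 1] happens only on output images**, never inside the
  solver, where it would bias C.
- **Optional seeded row subsampling** of the design matrix trades fit
  speed for estimator variance on large images; default is all rows.
- The training reference must span the color gamut to be restored: a
  correction fitted only on green foliage is unconstrained on the yellow
  subspace and will not preserve senescent colors. A color chart (or a
  scene containing senescent tissue) avoids this.

### Calibration references

Two routes produce the target G:

1. **Young-plant estimate** (`estimate_ground_truth`): young, unstressed
   plants are uniformly green, so edge yellowness must be distortion. The
   red channel — empirically the sharpest band at leaf edges — is
   thresholded by Otsu's method for an initial segmentation; an
   `override_mask` substitutes for interactive correction of that
   imperfect first attempt. Each leaf component is painted with the
   median color of its eroded interior (disk radius 2), the background
   with the median of user-designated sample regions, and blue
   support-frame components with their median color.
2. **Color chart** (`calibrate_from_chart`): each patch's pixels are
   paired with the chart's known colors. The cell margin excludes
   unreliable printed borders but should stay small (default 5% of the
   cell): pixels near patch boundaries are the ones whose neighborhoods
   span two colors and therefore carry the information about the blur.

### Ringing

Like any linear restoration, R = XC overshoots at sharp edges. The
artifacts here are bluish, spectrally distinct from every plant category;
the classifier assigns saturated blue hues (180–280°) to background, so
ringing does not contaminate the senescence estimate. Suppressing ringing
itself is out of scope.

## Senescence analysis

Restored (or clean) images are processed as:

1. **Segmentation.** A pixel is plant if its HSV color falls in any of
   the four category ranges below, outside the blue band. Components
   under 10 px are removed and holes of at most 5 px filled.
2. **Zoning.** The vertical span of the largest connected component
   (or a caller-supplied fixed span for cross-day comparability) is split
   into three equal-height bands: top, mid, bottom. Plant pixels below
   the span — fallen leaves — count as bottom; pixels above as top.
3. **Classification.** Default HSV ranges (hue in degrees):
   dark green hue [75, 165), V < 0.45; light green hue [75, 165),
   V ≥ 0.45; light yellow hue [40, 75); brown hue [10, 40), V < 0.6; all
   require saturation ≥ 0.40. In-mask pixels matching no range fall back
   to the nearest category centroid (circular hue metric), except
   saturated blue, which is background. Every range and the floor are
   YAML-overridable.
4. **Reporting.** Exact integer category counts per zone and overall;
   senescent percentage = 100·(light yellow + brown)/plant pixels. Zone
   counts sum to overall counts by construction and the overall
   percentage is identically the area-weighted zone mean.

The 0.40 saturation floor is the plant/background decision boundary:
palette-colored tissue stays above S ≈ 0.6 even under ±5% jitter, while
gray-ish soil/pot background and the partially-restored transition halo
around leaf silhouettes sit below 0.4. Without the floor these halo
pixels (predominantly green-hued, because green bleeds hardest under the
modeled distortion) inflate the plant area and bias the senescent
percentage low by several points at high senescence levels.

## Time series and scoring

Per-plant daily records (area, overall and per-zone percentages) feed:

- **Onset**: the first observed day whose overall percentage exceeds the
  threshold (default 1.0%) and stays above it for `persistence` observed
  days (default 2, to suppress single-frame noise). 1.0% matches the
  corrected baseline level on non-senescent plants.
- **Progression rate**: least-squares slope of percentage vs day from
  onset to the last observation, in percent per day.
- **Treatment summaries**: mean and sample standard deviation (n−1) of
  onset day and final percentage per group; plants without onset are
  counted and excluded from onset statistics.
- **Manual-score fit**: ordinary least squares of the 1–10 visual score
  on ln(percentage); R² equals the squared Pearson correlation of
  (ln p, s), so it is invariant to exchanging the regression roles. The
  natural log is a convention; the base does not affect R². The packaged
  chickpea table (32 pairs: two genotypes, four salt treatments, scores
  taken 2 and 3 days after the last imaging day, rows kept exactly as
  published including one repeated row) gives R² = 0.7576 for the 2-day
  scores and 0.5515 for the 3-day scores under this pooled fit —
  consistent with, though not identical to, the published 0.7503 and
  0.536, whose exact fit specification (pooling, exclusions) is not
  documented. The discrepancy is reported as-is rather than tuned away.

## Synthetic scenes

The generator renders what the analysis needs to be tested against, not
photorealism: 5–9 elongated, curved, tapering leaves fan out from a basal
point on a homogeneous dark background, optionally behind a blue support
frame; colors come from a six-entry palette (two greens, light yellow,
brown, background, frame blue) with ±5% per-channel jitter, chosen so the
categories remain separable under the default thresholds. Senescence is
planted leaf-wise — whole lowest leaves first, the marginal leaf turning
from its tip — which mirrors how senescence develops and is scored on
real plants and keeps the senescent region's perimeter-to-area ratio
comparable to the green foliage's. The realized fraction is exact up to
pixel rounding and is emitted with every scene, along with the plant
mask and per-pixel category map. Time series scale the same leaf
skeletons (area ∝ 1 + growth_rate·day) with the senescent fraction
following senescence_rate·(day − onset + 1) from onset; per-day seeds are
(seed·1000003 + 7919·day) mod 2³¹.

What the generator does *not* emulate: soil/pot texture, specular
highlights, overlapping plants, illumination gradients, leaf-level
self-shadowing, and real camera optics — the degradation is a linear
cross-channel kernel, which the (equally linear) correction can represent
exactly. Passing the synthetic suite therefore demonstrates correctness
of the estimator and the accounting, not fidelity on real imagery.

## Validation sizes and typical results

The test and acceptance runs use 256×256 scenes (128×128 for the 20-series
onset study; 13 days per series) so the whole suite completes in seconds.
Typical measured values: identity calibration residual ~1e-16; agreement
with an SVD pseudoinverse oracle to <1e-14; restored/distorted interior
RMSE ratio 0.38 ± 0.02 across seeds (range ≈ 0.34–0.42; the floor is the
noise gain ≈1.55σ of the fitted inverse over the noise-only background,
not fit bias); false senescence on a green plant ~4–12% before correction
and 0 after; end-to-end fraction recovery within ~2 points at planted
fractions up to 0.5; onset recovery 20/20 within ±1 day.

## Known limitations

- One correction matrix per camera setting; spatially varying distortion
  is out of scope.
- The correction is linear: it cannot beat the noise-gain/sharpness
  trade-off, and ringing is left unsuppressed (only excluded by color).
- Category boundaries are calibrated on the synthetic palette; real
  imagery will need the YAML config adjusted.
- The automatic red-channel segmentation is intentionally simple; on
  scenes where foliage is dark in the red band it under-segments and the
  override mask (or a chart) is the robust calibration route.
- Leaf fall produces non-monotone senescence trajectories; the onset rule
  handles noise via persistence but no leaf-tracking is attempted.
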