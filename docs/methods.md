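# Methods

This note documents the models, algorithms and numerical choices behind
`dpcscreen`, and what its synthetic validation does and does not show.

## The assay being modeled

Resting fibroblasts are thin spindles; upon stimulation (TGF-β1, the
"model" condition at 10 ng/mL) they activate into myofibroblasts:
enlarged, spread, α-SMA–positive and, around the model dose,
hyper-proliferative. The screen looks for compounds that keep stimulated
cells in the resting regime — morphologically control-like and with
proliferation suppressed back toward the control level — without being
cytotoxic. All readouts come from label-free digital phase contrast
(DPC) time series, so living cultures can be followed for 24–36 h at
30-minute intervals.

## Phantom generator

No real microscope data ships with the package; a generative model
produces two-channel (bright-field + DPC, optionally marker and nuclei)
fields with exact ground truth.

**Activation.** The probability that a cell is activated follows a Hill
curve in dose, `f(d) = f0 + (fmax − f0)·d^h/(d^h + d50^h)` with defaults
`f0 = 0.05`, `fmax = 0.9`, `d50 = 2.5 ng/mL`, `h = 1.5`. In
time-resolved simulations the fraction approaches its dose asymptote
with a first-order onset, time constant `τ = 10 h`, reflecting the
hours-scale induction of the activation program; the 24-h model-dose
condition then sits firmly in the activated regime (f ≈ 0.74) while the
12-h low-dose conditions are still partial — which is what makes the
dose/time class anchors meaningful.

**Marker.** Per-cell marker intensity (an α-SMA surrogate) is
`20 + 100·activated + N(0, 8)` arbitrary units. The DPC rendering
amplitude is mildly coupled to the marker (spread myofibroblasts have
more optical mass), which gives morphology–marker correlation structure
for the selection stage to find.

**Geometry.** Axis lengths (px at render scale 1): resting
major/minor ~ N(40, 8)/N(8, 2); activated N(45, 10)/N(25, 6) —
activated cells have ≈ 3.5× the area and much lower elongation. Cells
are placed with a soft repulsion (minimum centre separation
0.25·(major_i + major_j), best of 15 attempts) emulating
contact-inhibited monolayers; far beyond confluency placement degrades
gracefully to uniform.

**Rendering.** Each cell is a super-Gaussian elliptical profile
(`exp(−r³)` in normalized ellipse radius) with a brighter nuclear
centre, added over a noisy background (level 900, σ 25) with smooth
texture (σ 8 px, amplitude 18). Output is 16-bit; identical seeds give
bit-identical images.

**Proliferation.** Well cell number follows logistic growth with base
doubling time 24 h (NIH-3T3-like) and a dose-modulated rate multiplier:
1 at dose 0, peaking at 1.6 at 10 ng/mL, and suppressed (to ≈ 0.5) at
≥ 100 ng/mL — a unimodal, biphasic dose response. Well counts track the
logistic expectation with a 1 % lognormal well-level rate jitter;
per-field counts add a small (4 %) sampling jitter. Counts are not a
branching process: a plate-level Z′ above 0.5 on a ~3,000-cell/well
assay implies well-level count noise far below single-field branching
noise, and the deterministic-expectation model reproduces that regime.

**Planted effects.** Compound wells receive the model stimulus plus an
effect: *inhibitors* (strength s ~ U(0.85, 0.98) at the primary 10 μM,
scaled across concentrations by a saturating potency curve with
EC50 = 5 μM) pull both the activated fraction and the growth multiplier
toward control values; *toxic* compounds replace the growth multiplier
with U(−0.5, 0.4), driving counts below the control range.

## Segmentation

Background is estimated as a morphological lower envelope (grey opening
with a window larger than one cell, Gaussian-smoothed, clamped from
above by a robust global bound so near-confluent fields do not drag the
envelope onto the cells). After subtraction and smoothing (σ = 2 px at
native scale), the foreground threshold is anchored on the low tail of
the histogram — background level = 5th percentile, scale from the
2nd–16th percentile span — which stays background-dominated even at
high confluency. Touching cells are split by a marker-controlled
watershed seeded at maxima of the scale-normalized determinant of
Hessian (a blob detector: elongated cell bodies respond like ridges and
give ≈ 0 determinant, so only compact nuclear centres seed); seedless
components get their intensity maximum as a fallback seed. Objects
below `min_area` (60 px² at native scale, scaled by the square of the
render scale) are dropped; border-touching objects stay in the mask for
counting but are excluded from morphometry. On phantom time courses at
the count-validation density the label-free counts track ground truth
with ≈ 7 % mean absolute relative error; accuracy degrades above ~50 %
coverage, which is why simulated wells are seeded to stay sub-confluent
at the 24-h readout, as a real screen would be.

## Morphometry

Exactly 31 features per cell, in four documented groups: 10 shape
(area, Crofton perimeter, isoperimetric roundness 4πA/P² clipped to
(0, 1], best-fit-ellipse length/width, aspect ratio, solidity, extent,
equivalent diameter, eccentricity); 6 intensity (mean, SD, min, max,
radial mean over five normalized-radius bins, radial relative
deviation); 3 radial profile bands at normalized radius 0–⅓
(`profile_1`), ⅓–⅔ (`profile_2`) and ⅔–1 (`ebr_bright`); and 12
orientation-pooled Gaussian-derivative texture features — bright-spot
(relu(−LoG)), dark-spot (relu(LoG)), edge (gradient magnitude) and
ridge (difference of absolute Hessian eigenvalue magnitudes) at
smoothing scales 0 (raw pixels), 1 and 2 px, each the mask-restricted
mean response normalized by the image's robust intensity range. The
normalized radius uses the region's best-fit-ellipse frame. The
registry is order-stable and versioned; CSV headers follow it exactly.
These are structural analogues of commercial high-content features, not
numerical reproductions.

## Time series

Per-field feature summaries are means over cells (configurable), giving
a features × time "temporality matrix" (31 × 48 at 30-min intervals
over 23.5 h in the default configuration). Time points with zero cells
are filled by linear interpolation between populated neighbours
(nearest value at the edges; interpolation never extrapolates beyond
observed values). Proliferation curves are `N(t)/N(0)`; a well with no
cells at time zero is reported invalid rather than silently dropped.
Label-free counts are compared against a reference by per-time
two-sided t-tests with a "no significant difference" flag at α = 0.05.

## Marker linkage and PCA

Regressions are computed on condition-level means (doses, time points
or inhibitor concentrations), not per cell. r² is the squared Pearson
correlation; a zero-variance feature has r² = 0 by definition.
Selection uses strict `r² > 0.3`; the "common parameters" are the
strict intersection of the selections from the three contexts (dose
series, time series at the model dose, inhibitor series). Condition
profiles are z-scored before PCA; cluster membership is operationalized
as Mahalanobis distance to the control centroid in the retained
component space, thresholded at the 97.5th empirical percentile of the
control replicates' own distances (covariance regularized, with a
diagonal fallback when controls are few).

## Classifier

The preprocessing contract is fixed and tested independently of the
backend: bilinear-resize each of the two channels to target × target
(default 299), append a third channel equal to the element-wise mean of
the two resized channels (computed before normalization), then min–max
normalize each channel to [0, 1] (a zero-range channel maps to 0).

Labels come from dose/time anchors: vehicle is always type 0; the
default table maps the 1.25 and 2.5 ng/mL bands near 12 h to types 1–2,
the model-dose band near 12 h to type 3, and the 25 and 50 ng/mL bands
after 20 h to types 4 and 5. The generating conditions for the phantom
dataset anchor the high-dose classes at 24 h — the screen's decision
time point — so that dose-dependent growth separates them. A (dose,
time) pair outside the table raises an error rather than guessing.
Types group as {0,1} normal, {2,3} alternative, {4,5} fibrotic.

The training backend is a compact multilayer perceptron trained with
softmax cross-entropy and Adam under an epoch cap (default 120), on a
*fixed* (untrained) multiscale feature front end: per-channel intensity
histograms and supra-threshold areas, band-pass energy statistics and
spot/edge/ridge texture energies of the DPC channel, binary-morphology
composition proxies (thin-structure vs opened area, component counts),
nucleus-scale blob counts and skeleton length, the package's own
segmentation statistics (object count and log-area histogram), and a
coarse average-pooled spatial map. Features are standardized on the
training split. The front end is rotation-tolerant by construction and
the four-fold rotation augmentation covers the remainder. The dataset
generator uses 200 images per class at 96 × 96 (seeding ≈ 45 cells per
field, 4 % per-field count jitter) — chosen so the 24-h model-dose
condition stays below ~50 % confluency, as the real assay's seeding
density is designed to do. Splits and folds are stratified and
deterministic per seed; cross-validation reports macro
precision/recall/F1 with per-fold means and SDs.

One property of the prescribed dataset protocol deserves emphasis:
rotation augmentation is applied *before* the 4:1 split, so rotated
copies of one base image can land on both sides, and with a
rotation-invariant front end the validation set is then largely
in-sample — validation accuracy measures class separability under the
protocol rather than out-of-sample generalization.  The independent
generalization check is the planted-truth recovery study, whose screens
are generated from entirely fresh seeds.

## QC and hit calling

Z′ uses the standard form `1 − 3(σ_m + σ_c)/|μ_m − μ_c|` with sample
(n−1) SDs; equal group means are reported as a QC failure, not
swallowed. CV is `SD/mean × 100 %`. The default readout is the relative
cell count at 24 h. The cumulative filter uses empirical type-7
quantiles: hit ⇔ readout ≤ the model distribution's 5 % quantile *and*
≥ the lower bound of the control group's central 95 % interval; below
the control band ⇒ toxic-suspect; both levels are configuration. The
directionality (lower tail of the model group) encodes the screening
goal — anti-proliferative without cytotoxicity; a two-sided variant is
selectable. Per-compound decisions use a majority vote over that
compound's classified fields with ties broken toward the higher (more
fibrotic) type; step 2 requires the cumulative hit at the primary
concentration and PCA control membership at ≥ 1 of the confirmation
concentrations (20/10/5/1 μM); final hits are the strict intersection,
computed only on plates passing Z′ > 0.5. Dose confirmation (optional)
requires the hit criterion at ≥ 2 concentrations and reports the
Spearman readout-vs-concentration trend.

## Desk-scale study conditions

The validation studies in `dpcscreen.experiments` use deliberately
reduced problem sizes: QC plates simulate 8 control + 8 model wells per
plate with one 512 × 512 field per well at render scale 0.3 (≈ 250
cells per field at seeding, carrying capacity scaled accordingly); screens use 96 compounds over two 96-well
plates (12 control + 12 model wells each) with one 128 × 128
classification field matched to the classifier's training distribution
and three 256 × 256 readout fields per well; classifier training uses
200 images per class. Confirmation wells are simulated only for
compounds passing both the classifier gate and the cumulative filter —
the same funnel order the assay itself runs.

## What the phantoms do and do not show

The generator reproduces the statistical structure the pipeline relies
on — state-dependent geometry, marker–morphology coupling, dose- and
time-resolved activation, biphasic growth, plate layouts with reference
wells, planted effects with dose-scaled potency — and passing tests
demonstrate that the algorithms recover planted truth under those
assumptions. They do not demonstrate performance on real DPC data:
phantoms have no optical physics (no phase halos or shade-off), no cell
migration or tracking, no debris or imaging artifacts, no
compound-specific morphologies, and simplified texture. Segmentation
parameters were calibrated on phantoms only. The classifier's accuracy
bound holds for the phantom class-conditional distributions; real
inter-class overlap may be larger or smaller.

## Known limitations

* Frame-to-frame cell identity is not tracked; the generator persists
  cells only to make time series smooth.
* Counting degrades above ~50 % confluency; well seeding in the studies
  is chosen to avoid that regime, and very dense real cultures would
  need a stronger splitting model.
* The r² marker screen applies no multiple-testing correction (by
  design, matching the analysis it models).
* The Mahalanobis membership threshold is an empirical quantile of few
  control replicates and is therefore conservative-noisy; with < 3
  controls it falls back to a diagonal covariance.
* One training backend ships (the MLP head over fixed features); the
  module boundary admits other backends behind the same train/classify
  surface.
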