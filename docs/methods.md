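# Methods

This note documents the models, conventions and numerical choices behind
`pigmorph`, and what the synthetic experiments do and do not demonstrate.

## The estimation problem

A fixed camera looks straight down at a weighing channel; one pig at a time
walks through. An upstream instance-segmentation network (outside this
package) produces a mask of the animal's back per frame. The task is to
map that mask, plus a small table of per-animal measurements, to live
weight. Two physical effects dominate the error budget:

* **Pinhole scaling.** The animal's apparent size depends on the
  camera-to-back distance `Hdep = Hg − (Hb + Hh)/2`; a tall pig stands
  closer to the lens and looks larger. The background fraction of the
  frame (Dev) is a monotone proxy for this distance.
* **Spine bending.** A bent body projects a shorter chord than its true
  length: an arc of length `L` and curvature `κ` spans
  `(2/κ)·sin(κL/2)`. Raw pixel body-length and hip-width proxies are
  therefore biased low on bent frames; the correction stage is the fix.

## Mask processing conventions

* Foreground is 8-connected, background 4-connected; coordinates are
  0-based (row, col).
* Thresholding: foreground iff intensity > threshold (default 0, so any
  nonzero label counts as animal); colored multi-channel rasters collapse
  with a per-pixel channel max first.
* The "size 70" elliptical structuring element is interpreted as a
  diameter: the centred discrete disc of Euclidean radius 35 on a 71×71
  grid. A literal even-sized 70×70 element has no centre pixel and would
  shift the result by half a pixel; the centred odd disc is shift-free and
  makes opening exactly equal to the disc sliding min/max filter. The
  element size is a parameter (`kernel_size`) for users who want other
  diameters.
* Opening is computed with exact Euclidean distance transforms
  (background-padded), which is mathematically identical to erosion
  followed by dilation with the disc but linear-time in the image size.
  The brute-force min/max filter remains in the test suite as an
  independent oracle.
* The boundary is traced with Moore-neighbourhood tracing, clockwise,
  starting at the topmost-then-leftmost foreground pixel, terminated by
  Jacob's criterion. This fixes the perimeter value deterministically.

## Shape features

Area is the foreground pixel count; Dev is exactly `1 − Area/(H·W)`.
Perimeter is the √2-weighted chain length of the traced boundary (the sum
of segment lengths between consecutive boundary pixels), not an edge
count. The minimum-area rotated rectangle is computed by rotating
calipers: the optimum has a side collinear with a convex-hull edge, so
scanning hull-edge orientations over the pixel-centre hull is exact;
PBL ≥ PHW by convention. Eccentricity comes from the region's second
central moments with the per-pixel 1/12 (unit-square) correction; with
principal moments l₁ ≥ l₂ it is √(1 − l₂/l₁). For digital ellipses with
axis ratios 1–3 this matches the analytic value to better than 0.02.

## The correction stage

Three Newton-boosted tree regressors (the package's own implementation,
defaults: 300 rounds, learning rate 0.1, λ=1, γ=0, depth 4) map per-frame
image features to the measured body length, hip width, and the Eq.-style
camera distance `Hdep` (computed from measured heights and the camera
height, default 145 cm). Design choices:

* **Inputs.** The default input set is {PBL, PHW, Dev}. `Hdep` is a
  *target*, not an input: at inference time only image features are
  available. `include_hdep_input=True` restores the literal protocol for
  users who do have measured heights at inference.
* **Split hygiene.** The correction model is fitted on training-split
  frames only; corrected features for held-out frames come from that
  fitted model. Nothing in the held-out rows influences training.
* **Units.** Corrected outputs are in cm; the raw pixel proxies stay in
  pixels (strategy 1 uses them as-is).

## Regression models

Trees split on variance (SSE) reduction — the standard regression
impurity; entropy-based information gain is undefined for continuous
weight targets. Ties break to the lowest feature index, then the lowest
threshold (thresholds are midpoints between consecutive distinct values).
The forest prediction is the exact arithmetic mean of its trees; each tree
sees a seeded bootstrap sample and draws a fresh feature subset per split
(default fraction 1/3). The boosting implementation is second-order with
squared loss: gradients `g = ŷ − y`, hessians 1, split gain
`½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ` (splits with non-positive
gain are rejected), leaf weights `−G/(H+λ)`, shrinkage η per round. With
γ = 0 and η ≤ 1 the training RMSE is non-increasing per round, which the
tests verify, and a single-leaf round reproduces the closed form
`−G/(n+λ)` exactly.

Of the ten registry methods, LR (normal equations), lasso (cyclic
coordinate descent, tolerance 1e-8, sklearn's 1/(2n) objective
convention), kernel ridge (closed form, RBF default), AdaBoost.R2 (linear
loss, weighted-median prediction) and stacking (out-of-fold base
predictions from {forest, boosting, KRR} into a linear meta-learner) are
implemented natively. SVR, MLP and BP (a single logistic hidden layer
trained by SGD — the classic back-propagation network) delegate to
scikit-learn behind a standardising adapter; their internals are not part
of this package's contribution. Native models serialize to a JSON
tree/coefficient dump; adapter models must be refitted from their spec and
seed.

## Evaluation protocol

7:3 train/test split (train size ⌊0.7n⌋, seeded permutation). The default
granularity is by-frame, mirroring the original protocol; a by-pig mode is
available and recommended when generalisation to unseen animals is the
question, because frames of one pig are highly correlated and a by-frame
split lets models partially memorise animal identity. Grid search is
exhaustive and scored by mean five-fold CV RMSE on the training split
only; ties go to the first grid point. Metrics: MAE, MAPE (percent), RMSE
and R². The R² baseline is the mean of the *observed* values by default;
`r2_baseline="predicted"` switches to a predicted-mean baseline for users
who want that variant. MAE ≤ RMSE always holds; MAPE requires strictly
positive targets.

## The synthetic herd

The generator emulates the study conditions: 39 pigs, ≈39 frames each
(1521 frames vs the original ~1505), trait marginals matching the study
herd (weight 122.81 ± 7.86 kg in [104, 138]; BL 126 ± 5.79 cm; HW
34.28 ± 1.72 cm; Hb 69.4 ± 2.0 cm; Hh 75.13 ± 2.55 cm), body bending, and
pinhole camera-distance scaling at 1920 × 1080.

* **Trait correlations.** The four linear traits load on a shared latent
  size factor with pairwise correlation 0.6; draws outside a trait's
  [min, max] are rejected and redrawn per pig.
* **Allometry.** Weight = s·BL·HW²·Hb·exp(ε), ε ~ N(0, 0.02), clipped to
  the weight bounds. The squared width term is the classical heart-girth
  allometry (mass grows with length times girth squared) and is what makes
  slender animals lighter at equal size — without it the eccentricity–
  weight correlation would be near zero and sign-unstable, contradicting
  the documented behaviour of the Ecc feature. The scale s is calibrated
  by a deterministic internal Monte-Carlo fixed point (fixed internal
  seed, 2000 pigs) so that the mean *generated* weight equals 122.81 kg;
  a naive trait-means calibration would sit ≈2 kg low because the joint
  rejection on trait bounds (the BL maximum lies only +1.9 SD above its
  mean) and the final clipping both pull the realized mean down. With all
  SDs zero the calibration degenerates to the exact trait-means value.
  Under these constraints the emergent weight SD (≈12 kg) exceeds the
  nominal 7.86 kg; trait marginals and the weight SD cannot both be
  matched by any smooth multiplicative law at trait correlation 0.6, and
  the trait marginals take precedence.
* **Body shape.** A capsule (stadium): spine arc of length BL − HW swept
  with radius HW/2, so the straight body is exactly BL long overall and
  the analytic area is BL·HW + (π/4 − 1)·HW². Curvature is half-normal
  (SD 0.004 cm⁻¹ — visible bending on roughly a third of frames); pose is
  a uniform random rotation with a bounded centre jitter. `Hdep` is fixed
  per pig (no per-frame posture height variation by default).
* **Camera.** Pinhole with `pixels_per_cm = focal_scale / Hdep`;
  `focal_scale` defaults to 400 px·cm, i.e. ≈5.5 px/cm at the herd-mean
  distance of 72.7 cm, chosen so the largest plausible pig fits a
  1920 × 1080 frame at any rotation. Rasterization marks the spine
  polyline on the pixel grid and thresholds an exact Euclidean distance
  transform at HW/2; optional seeded edge noise perturbs the local radius.
* **Frame allocation.** The original frame total (1505 over 39 pigs) is
  not divisible; the generator uses a uniform frames-per-pig count
  (default 39, giving 1521).

**What the synthetic experiments show — and do not.** Passing tests
demonstrate that every stage is internally correct (against closed forms
and independent oracles) and that the pipeline recovers weight under the
generator's assumptions: smooth allometry, clean capsule masks, exact
ground-truth biometry, a single fixed camera. They do not demonstrate
performance on real farm imagery, where segmentation errors, irregular
body outlines, posture height changes, motion blur and measurement error
in the biometry all add error sources the generator deliberately omits.
On frame-level splits the reported held-out errors are flattered by
animal-identity memorisation (39 distinct animals); by-pig splits are the
honest generalisation test.

## Problem sizes and runtimes

The default test suite renders small frames (960 × 720) for the per-stage
tests and runs one full-scale end-to-end check (39 × 39 frames at
1920 × 1080, ≈4 minutes on one CPU). `scripts/acceptance.py` re-runs the
full-scale study with both ensemble regressors in roughly five minutes.

## Known limitations

* Single animal per frame; no occlusion, no multi-instance selection.
* The correction stage presumes the biometry table covers every pig seen
  at training time.
* MAPE is undefined at zero weight (never occurs for live animals).
* AdaBoost.R2 uses weighted bootstrap resampling, so unlike the other
  native learners its fitted trees depend on the resampling draw (still
  seed-deterministic).
* The sklearn-backed registry entries (SVR, MLP, BP) do not serialize to
  the JSON dump; refit them from their spec and seed.
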