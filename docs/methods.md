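# Methods

This note records the models, conventions and design choices behind
`tonguefusion`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cohort model

The generator emulates a two-group (normal / type-II diabetes) screening
study of 80 subjects per group with a 1:2 male:female ratio.  Every
demographic and biochemical variable — age, waist, hip, BMI, systolic and
diastolic blood pressure, fasting and postprandial glucose, HbA1c, tongue
temperature — is drawn from an **independent per-group normal
distribution** whose mean and SD are the package defaults
(`GROUP_PARAMS`).  Only first and second moments of such study populations
are typically reported; the within-subject correlation structure between,
say, HbA1c and fasting glucose is unknown, so independence is assumed and
documented here.  Draws are clipped below at 0 to keep physiological
values positive; the tongue temperature is *not* clipped to the thermal
display scale at sampling time, because truncating the diabetic
distribution (35.86 ± 0.80 °C against an upper scale limit of 36.9 °C)
would bias its mean downward by ≈ 0.04 °C and distort the printed moments
the generator is supposed to reproduce.  The clip to [28.5, 36.9] °C is
applied where it physically belongs: in the temperature → intensity
mapping of the renderer.

### Image model

*Thermal frame* (240 × 320 array = 320 × 240 px): a dark backdrop
(intensity 8, emulating the black cloth used in acquisition protocols) and
an elliptical tongue (semi-axes 85 × 70 px).  The interior intensity is
`255 · (T − 28.5)/8.4` — the fixed 28.5–36.9 °C display scale — flat out
to 55 % of the ellipse radius and fading 30 % toward the rim, so the
central 50 × 50 ROI (which reaches normalized radius ≈ 0.46) tracks the
subject's temperature exactly linearly.

*Visible frame* (280 × 390 × 3): the same tongue geometry in a pinkish
base color with per-subject color jitter (SD 5 per channel), plus a
whitish coating ellipse centered in the upper-to-middle tongue region
(overlapping the top of the ROI) whose amplitude is drawn per subject
around a group level of 22 (normal) vs 38 (diabetes) intensity units,
SD 8 — a deliberately overlapping effect, since visible-only tongue
classification is reported as weak in this literature.

*Shared structure*: a midline sulcus plus three lateral fissures (confined
to an annulus outside the ROI so they never perturb ROI statistics), and a
per-subject band-limited "papillae" texture field (Gaussian-filtered noise,
σ = 2.5 px, expressed with gain 6 in the thermal and 12 in the visible
frame).  Both appear in both modalities because they are properties of the
tongue surface; they are what makes the rotational component of
registration identifiable, exactly as real surface texture does.

*Misalignment*: the visible scene is built on the common 240 × 320 grid,
rigidly displaced by a uniform translation (|dx|, |dy| ≤ 10 px) and
rotation (|θ| ≤ 5°), then upsampled to its native 280 × 390 size.
`ImagePair.true_offset` therefore lives in thermal-grid pixels and
survives the preprocessing resize up to interpolation error (the slight
aspect-ratio anisotropy, 390/320 vs 280/240, perturbs a 5° rotation by
about 0.2°).  Additive Gaussian pixel noise (SD 3 intensity units, a
config knob) is applied to both frames, after which they are rounded to
8-bit.

What the generator does **not** emulate: photorealistic tongue anatomy,
FLIR palette rendering, emissivity/evaporation physics, specular
highlights, intra-image temperature gradients of clinical origin, or any
correlation between coating and biochemistry beyond the group label.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers effects of the modeled kind and size — not
clinical performance on real images.

## Preprocessing

Grayscale conversion uses the BT.601 weights (0.299, 0.587, 0.114), which
sum to one.  The visible frame is resampled (bilinear) onto the thermal
grid rather than the reverse: thermal is the lower-resolution modality and
upsampling it would fabricate detail.  Registration maximizes normalized
cross-correlation over an exhaustive discrete family — every integer
translation within ±12 px (evaluated simultaneously via FFT
cross-correlation) at every rotation in ±5° step 0.5°, then a local 0.1°
rotation refinement.  The correlation is computed on high-pass filtered
images (original minus a σ = 2 Gaussian blur): the smooth tongue
silhouette is nearly rotation-invariant and, if left in, biases the
recovered rotation toward zero by roughly 10 %; raw-intensity NCC remains
available (`highpass_sigma=None`).  The identity transform is always a
candidate, evaluated under the exact Pearson measure, so registration can
never reduce similarity.  Recovered transforms are compared against the
*rigid inverse* of the injected offset — the inverse of
(rotate θ, translate t) is (rotate −θ, translate −R(−θ)t), which differs
from −t by up to ~1.2 px at the extremes of the injected range.

The ROI is placed fully automatically at the geometric center
(⌊m/2⌋, ⌊n/2⌋) with an explicit `(row, col)` override; a
semi-interactive placement cannot live in a tested pipeline.  All indexing
is 0-based `(row, col)`; in rigid transforms `dx` moves along columns and
`dy` along rows, with positive angles counterclockwise.

## Fusion

Two-level db2 decomposition with **symmetric (half-sample) extension**
(configurable).  Symmetric extension keeps constant images constant, which
in turn makes the identity-fusion and constant-image results exact; the
analysis/synthesis pair reconstructs any image to < 1e-8.  A rule "A-B"
applies operator A to the deepest approximation band and operator B to all
six detail bands (three orientations × two levels); `mean` is (a+b)/2,
`max`/`min` are elementwise extrema.  All nine rules are symmetric in the
two inputs and idempotent (fusing an image with itself returns it).  The
often-quoted prescription "low frequencies from the visible image, high
frequencies from the thermal" is a *selection* rule, not an elementwise
one; it is provided separately as `combine_select` and is deliberately not
among the nine.  Fusion operates on float coefficients of float images;
clipping/rounding to 8-bit happens only in `to_uint8`.

## Texture features

GLCM defaults: 8 gray levels uniformly quantizing [0, 255], single offset
(0, 1) (distance 1, angle 0°), symmetric (transpose-added), normalized.
Integer input whose maximum is below the level count is treated as
already-quantized gray-level indices (the skimage convention).  Energy is
Σp² itself (not its square root), entropy is in bits, homogeneity uses
1 + |i−j| in the denominator; correlation of a flat ROI is defined as 0.
First-order moments are population moments; skewness is m₃/m₂^1.5 and
kurtosis is excess (m₄/m₂² − 3), both 0 for zero variance.  GLCM counting
is implemented directly (a bincount over index pairs) because the
established library supports only distance/angle offsets and differs in
its energy/homogeneity conventions; it is used as an independent
cross-check where the conventions agree.

## Quality metrics

NCC and NAE are implemented with ratio-of-sums denominators
(ΣXY/ΣX², Σ|X−Y|/ΣX): the per-element reading is numerically unstable near
zero pixels and does not yield NCC = 1 for identical images, which the
ratio-of-sums form does.  The SNR formula (reference energy over error
energy, in dB) is the standard member of the PSNR family.  SSIM is
evaluated **globally** — one mean/variance/covariance triple per image,
with C₁ = (0.01·255)², C₂ = (0.03·255)² — matching the single-statistic
form used for whole-image fusion assessment; the sliding-window mean-SSIM
is available behind `windowed=True`.  PSNR and SNR return `inf` at zero
error rather than an arbitrary cap.  "Before fusion" compares thermal
against visible; "after fusion" compares the fused image against each
source and averages, with per-source values always retained.  Rule
selection averages after-fusion MSE/PSNR over pairs and picks the minimum
MSE (ties: maximum PSNR, then canonical rule order mean-mean, mean-max, …).

## Classification

Linear-kernel SVM (C = 1), shrinkage-free LDA, and k-NN (k = 5, Euclidean)
— hyperparameters exposed in `train_eval`.  Splits are stratified 70/15/15
with floor rounding on validation/test and the remainder to training,
which reproduces both canonical splits exactly (160 → 112/24/24,
960 → 672/144/144).  Features are z-scored with statistics fitted on the
training split only (no leakage).  Welch's unequal-variance t-test is used
for group comparison because the two groups' SDs differ several-fold for
the glycaemic variables; variables that are constant and equal across
groups report t = 0, p = 1.  Evaluation uses the held-out 15 % test split;
the validation split is reserved for hyperparameter sweeps.

## Problem sizes and determinism

Default experiment sizes were chosen so that a complete run is a desk-scale
computation: the classification regression uses 10 seeds × 40 subjects
(≈ 6 test subjects per seed, so per-seed accuracies are coarse and the
fused-vs-visible comparison is made on the 10-seed mean), the registration
recovery check uses 100 rendered pairs, and distribution-recovery checks
use 2000 subjects per group, where the Monte-Carlo SE of the temperature
difference is ≈ 0.02 °C.  Every stochastic component takes an explicit
seed (`numpy.random.default_rng`); per-subject render seeds are derived
from the study seed, so whole studies are bitwise reproducible.

## Known limitations

* Independence across biochemical variables understates real
  multicollinearity; classifier accuracies on this cohort are not clinical
  estimates.
* Rigid-only registration; no deformable motion, no tongue segmentation
  beyond the fixed central ROI.
* Single-offset GLCM (no rotation-averaged Haralick battery), single
  wavelet family (db2; other `pywt` wavelets work but are untested beyond
  smoke level).
* The fusion-rule ranking on synthetic cohorts reflects the generator's
  image statistics; on these smooth renders mean-approximation rules win
  MSE almost by construction.
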