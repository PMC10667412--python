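# Methods

This note documents the models and procedures `focusedview` implements,
the choices made where the design was genuinely open, and what the
synthetic phantoms do and do not establish.

## Problem and pipeline

A stroke-protocol CT angiography (CTA) covers the aortic arch to the
cranial vertex, so it visualizes far more anatomy than the arteries the
stroke read-out needs. The focused-view approach segments two classes on
the CTA volume —

* **class 1** — the cranial cavity and proximal spinal canal (brain,
  intracranial arteries, dural sinuses), annotated at cavity level rather
  than vessel level;
* **class 2** — the extracranial stroke-related arteries (aortic arch,
  subclavian, common/internal carotid and vertebral artery lumina up to
  the skull base);

and then blanks every voxel outside the predicted segmentation to
−1000 HU (air), leaving a "focused view" CTA that shows only
stroke-relevant structures. The pipeline is: in-plane resampling →
per-volume intensity normalization → patch-based training of a 3-D
segmentation network per cross-validation fold → sliding-window
inference with overlap averaging → probability averaging across the fold
ensemble → argmax labels mapped back to the native grid → masking →
DICOM export.

## Segmentation networks

Two architectures are provided, both mapping a single-channel HU patch of
the configured window to per-voxel softmax probabilities over the three
classes:

* **basic 3-D U-Net** — encoder/decoder with two 3×3×3 convolutions
  (optionally instance-normalized) + ReLU per resolution level, 2×2×2 max
  pooling, nearest-neighbour upsampling with skip concatenation, and a
  1×1×1 softmax head.
* **dual-attention U-Net** — the same backbone with two parallel
  self-attention blocks at the bottleneck: a position-attention block
  (affinity over flattened bottleneck voxels, query/key at a quarter of
  the channel width) and a channel-attention block (affinity over
  channels). Each block is residual with a learnable scalar gain
  initialized at zero, and their increments are summed, so an untrained
  dual-attention network computes the same function as the basic one
  while carrying strictly more parameters. Placement at the bottleneck
  only keeps the quadratic attention cost negligible.

The layer stack (im2col convolution, instance norm, pooling, attention,
softmax, Adam/RMSProp) is implemented directly on numpy with manual
backpropagation; every layer's gradient is validated against central
finite differences in the test suite, and the whole network's gradient is
checked end-to-end in float64. Weight init is He-normal; L2 regularization
is applied to weight tensors only (not biases or normalization gains).

## Loss, training and ensembling

The loss is the mean categorical dice loss over the two foreground
classes,

    L = 1 − (1/2) Σ_{c∈{1,2}} (2 Σ_v p_cv g_cv + ε) / (Σ_v p_cv + Σ_v g_cv + ε),

with one-hot truth `g`, smoothing `ε = 1e−6`, pooled over the batch. Its
gradient with respect to the probabilities is computed in closed form and
pushed through the softmax.

Patch sampling has no natural epoch boundary, so an "epoch" is a fixed
number of sampled batches (configurable; 50 at full scale). Crops are
uniformly random; all-background crops are re-drawn a bounded number of
times by default (rejection can be disabled). After each epoch the model
is scored by the mean foreground Dice over the full validation scans via
sliding-window inference, the best-scoring weights are checkpointed, and
training stops after a patience of 50 epochs (full scale) without
improvement. Any improvement (> 0) counts.

Cross-validation uses five folds whose validation sets are disjoint
draws of 10% of the scans (90/10 train/validation per fold); the five
best-per-fold models form an averaging ensemble — the arithmetic mean of
member probability maps, which needs no renormalization. With a 10%
validation fraction and five folds, 50% of scans ever serve as
validators; the package also exposes the validation fraction for other
splits.

## Inference and masking

Sliding windows are placed at stride `window × (1 − overlap)` per axis
(default overlap 0.5), with the final window snapped to the far edge;
each voxel's probability is the unweighted mean over the windows covering
it (no Gaussian weighting). Volumes smaller than the window are padded
with the normalized image of −1000 HU and cropped after prediction.
Labels are the per-voxel argmax with ties broken toward the lowest class.
Predictions computed on the resampled grid are mapped back to the native
grid by nearest neighbour, because the mask is applied to the original
CTA, never the resampled one. Masking replaces label-0 voxels by exactly
−1000.0 and leaves all other voxels bit-identical; it is idempotent.

## Tuned hyperparameters

The shipped full-scale default configuration is: in-plane spacing 0.7 mm
(through-plane spacing is never resampled), per-volume z-normalization,
window 160×160×48, dual-attention architecture, instance norm on, batch
size 13, learning rate 4e−4, L2 2e−4, RMSProp, rotation/tilt/noise
augmentation frequencies 0.25 / 0.04 / 0.60, noise factor 0.003. The
search space spans spacing {0.5, 0.7, 1.0}, normalization {z-norm, divide
by 1000}, window XY 160–256 (step 32), window Z 16–64 (step 16), both
architectures, batch 1–15, learning rate and L2 in [1e−4, 1e−3]
(log-uniform), both optimizers, instance norm on/off, rotation and tilt
frequencies [0, 0.5], noise frequency [0, 0.7], and noise factor
[1e−4, 1e−2] (log-uniform). Search trials train a single fold under an
epoch cap and are scored by the best mean validation dice; sampling is
seeded uniform random over the space, validated by a planted-optimum
recovery test. Rotation/tilt magnitudes accompany the frequencies as
±15° in-plane and ±5° out-of-plane defaults; the noise factor is the sd
of additive Gaussian noise in post-normalization intensity units.

## Synthetic phantoms

The phantom generator makes the entire pipeline testable without patient
data. Each phantom has an air background fixed at −1000 HU, a soft-tissue
neck column containing a vertebra-like bone cylinder, a spherical bone
skull enclosing a brain ellipsoid (the cavity interior is class 1,
including any intracranial vessel course), and a configurable number of
contrast-opacified tortuous vessels (default 400 HU, radii 1.5–3 mm)
whose spline centerlines climb from the inferior arch region to the
skull base with a helical perturbation in the upper third and a drift
toward the vertebral column — deliberately creating vessel-near-bone and
vessel-through-bone configurations, the recognized hard case. Focal
stenoses narrow the lumen with configurable probability. Default HU
means (air −1000, soft tissue 40, brain 30, bone 1000, vessel 400) are
plausible CTA values, not measurements. Texture comes from additive
Gaussian noise (default sd 10 HU). Generation is bit-deterministic given
the spec seed, and the rasterized vessel volume is testable against the
analytic tube volume of the generated centerlines.

What the phantoms do **not** emulate: named arterial segment anatomy
(C1–C7/V1–V4), contrast-bolus dynamics, beam hardening, metal artifacts,
patient motion, or the HU overlap statistics of real tissue. Passing the
phantom-based learning check therefore shows that the implementation
trains, checkpoints, ensembles and infers correctly on a task with the
right structure — it does not certify clinical segmentation accuracy.

## Reduced-scale study conditions

Training the full-scale configuration is a GPU-days workload, so the
repository's tests and acceptance script exercise a reduced setting
chosen once: 20 phantoms on a 48×48×64 grid at 1 mm spacing (16 train /
2 validation / 2 held-out), dual-attention U-Net with window 32×32×16,
8 base filters, depth 2; RMSProp at learning rate 2e−3, batch 3, 15
batches per epoch, 26 epochs, no augmentation; z-normalization at 1 mm
in-plane spacing; evaluation by sliding window at overlap 0.5. The
learning rate is higher than the full-scale default because the reduced
network is ~100× smaller and the phantom task is intensity-dominated;
2e−3 converges in ~20 epochs where 4e−4 needs several times more. Under
these conditions the held-out mean Dice is ≈ 0.94 (cranial cavity) and
≈ 0.88 (extracranial arteries) — comfortably above the 0.8 / 0.6
thresholds the test suite asserts.

## Statistics

* **Dice coefficient** `2|A∩B|/(|A|+|B|)` per class, defined as 1 when
  both maps are empty; for one-hot inputs it is the exact complement of
  the dice loss as ε→0 (tested).
* **Wilcoxon signed rank** (paired, two-sided): zero differences dropped
  by default (Pratt variant available); midranks of |differences|; for
  n ≤ 25 the exact two-sided p is computed by dynamic programming over
  the 2^n sign assignments (doubled midranks are integers, so ties are
  handled exactly); for larger n a tie-corrected normal approximation
  (mean Σr/2, variance Σr²/4) without continuity correction.
* **Mann-Whitney U** from midranks; exact for small tie-free samples,
  otherwise tie-corrected normal approximation without continuity
  correction. Identical single-valued samples return p = 1.
* **Yates chi-square** on 2×2 tables by the closed form
  `N(|ad−bc|−N/2)²/((a+b)(c+d)(a+c)(b+d))` with the continuity term
  floored at zero and p from the χ²₁ survival function; χ² = 0 gives
  p = 1; a zero marginal raises.
* **Cohen's weighted kappa** with linear (default) or quadratic
  disagreement weights over categories 1–5; undefined (raises) when both
  raters use one identical category. Cross-checked against an
  independent implementation in the tests.
* **Score summaries** use inclusive linear-interpolation quantiles, which
  produce half-integer medians on small even samples (e.g. [2,2,3,3] →
  2.5), formatted as `m (IQR: a–b, range: c–d)`.

Both rank tests hold their type-I error at α = 0.05 within [0.035,
0.065] under 2000-replicate null simulations (asserted in the suite).

## Numerical and degenerate-input choices

DICOM export stores unsigned 16-bit values with RescaleSlope 1 and
RescaleIntercept −1024, so −1000 HU is the exact stored integer 24 and
round trips bit-exactly; arbitrary HU round-trip error is bounded by the
0.5 HU rounding quantum. NIfTI round trips are lossless. Label
resampling is nearest-neighbour everywhere; image resampling is linear
in-plane only. z-normalization statistics are computed once per whole
volume before cropping and recorded so inference applies the identical
transform; z-normalizing a zero-variance volume raises. Argmax ties break
toward background. Probability maps must sum to 1 per voxel within 1e−4
(float32 accumulation).

## Known limitations

The numpy layer stack is single-threaded GEMM-bound and intended for the
reduced desk-scale configurations; full-scale training (window
160×160×48, depth 4) is defined and constructible but not practical on
one CPU. The hyperparameter search is plain random sampling, not
adaptive. The DICOM writer emits uncompressed CT Image Storage only, and
the reader assumes one axial series per directory with uniform slice
spacing. Phantom realism limits are listed above; no claim about
reader-perceived visibility of real anatomy follows from any test here.
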