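# Methods

This note records how `lprseg` models the canopy-quantification problem,
the parameters that matter, and the choices made where the design was
genuinely open.

## Problem and model

Every pixel of an RGB canopy image is assigned one of three classes —
background (0), leaf (1), panicle (2) — by a fully convolutional network,
and the leaf-to-panicle ratio of the image is the count ratio
`LPR = L / P` of leaf to panicle pixels.  Classes follow the channel order
background, leaf, panicle everywhere (masks, probability maps, confusion
matrices, loss weights).

### Network

The backbone is an 18-layer-style residual network (basic blocks of two
3×3 convolutions; `backbone_depth` blocks per stage) modified for dense
prediction: the stem is a single stride-1 3×3 convolution + batch norm +
ReLU, there is no pooling before the first stage, and the four stages
C2–C5 use strides {1, 2, 2, 2}, so their cumulative down-sampling rates
are {1, 2, 4, 8} instead of the classification-network {4, 8, 16, 32}.
Thin leaf blades (a few pixels wide) and small grains would not survive a
4× stem reduction; this is the central architectural adaptation.

A top-down pathway forms the feature pyramid: each stage passes through a
1×1 lateral convolution to a common width (`stage_channels`, default 32;
interpreted as both the backbone stage width and the pyramid width, since
lateral 1×1 connections require a common channel count), and each coarser
level is 2× nearest-neighbor up-sampled and added to the next lateral.
The fusion head bilinearly up-samples P3/P4/P5 by factors 2/4/8 (bilinear
was chosen over transposed convolution for cost), refines each with a 1×1
convolution, concatenates with P2 (P2 enters the concatenation directly,
without its own refinement) into a 4×`stage_channels` tensor, applies a
3×3 convolution (width preserved) + batch norm + ReLU, and a final 1×1
convolution to 3 logits.  Per-pixel softmax gives the probability map;
prediction is the arg-max with ties resolved toward background.

The network is implemented directly in NumPy (float32).  Convolutions are
evaluated as one BLAS GEMM per kernel tap over the zero-padded input with
shifted accumulation, which avoids im2col's 9× memory cost; the same
decomposition yields exact weight and input gradients.  A directional
finite-difference check of the full assembled network is part of the
development tests of record (relative error → 0 as the step shrinks).

### Initialization and optimization

Convolution kernels use variance-scaling (He) normal initialization; batch
norm starts at scale 1, shift 0.  A literal zero-scale initialization
(`zero_scale_bn=True`) is available for study but zeroes all normalized
activations at the start of training, so it is not the default.
Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at a constant base learning
rate of 1e-3, mini-batch 24; an optional step decay
(`decay_epochs`/`decay_factor`) is available.  The best epoch by
validation mIoU is restored at the end of training (final train loss when
no validation split is given).  All randomness — weight initialization,
batch order, augmentation draws, data generation — flows from explicit
integer seeds, so runs are bit-reproducible.

### Loss

The multi-class focal loss, averaged over pixels:

    L = mean_px [ −α_c (1 − p_c)^γ log p_c ],   c = true class.

γ = 2 by default; α defaults to the inverse pixel frequency of the
training labels normalized to mean 1 (background dominates canopy scenes
at ~60–70% of pixels, panicle is rarest at ~10%).  The log is clamped at
1e-12.  Gradients with respect to the logits are analytic.  With γ = 0 and
uniform α the loss is exactly cross-entropy; this reduction and a
hand-evaluated single-pixel value are asserted in the tests.  Internally
the softmax for the loss is taken in float64 so these identities hold to
1e-9 even on float32 logits.

## Data pipeline

Training patches are random rectangles with sides drawn independently and
uniformly from [150, 600] pixels (height and width separately — field
patches were irregular, so rectangles are allowed), cropped identically
from image and mask, resized to a square `target_size` (bilinear for the
image, nearest-neighbor for the mask so labels stay categorical), and
normalized to [0, 1] by division by 255.  Augmentations fire independently
with probability 0.5 each: horizontal/vertical flips and 90° rotations act
on image and mask together; histogram equalization and multiplicative
brightness U(0.7, 1.3) with clipping act on the image only.  Equalization
is applied on the value channel of an HSV conversion (hue-preserving, so
class color cues survive) and, when both fire, before the brightness draw;
the order is a fixed convention.  Crop boxes are 0-based, half-open
`(row0, col0, height, width)`.

## Synthetic canopy generator

No field imagery ships with the package; the generator produces the study
conditions.  It emulates the structural contrast the segmenter must learn:

* **Leaves**: quadratic Bézier spines with random length (0.45–0.95 of the
  canvas side), curvature and orientation, stroked with a width profile
  tapering from 4–9 px at the base toward the tip, with slight lengthwise
  shading.
* **Panicles**: 25–70 overlapping grain disks (radius 2–4 px) scattered
  around a drooping branch arc — granular texture against the leaves'
  smooth elongation.  Panicles are drawn after leaves by default (they
  overtop the canopy at grain filling); occlusion is consistent between
  image and mask, which is the exact rendering record.
* **Background**: soil-brown base with low-frequency mottle plus fine
  grain.
* **Color regimes**: stage presets GG (green panicle + green leaf), YG
  (yellow panicle + green leaf, the default), YY (yellow panicle + yellow
  leaf).  No quantitative color statistics exist for these regimes, so the
  presets are plausible hues, documented as such.  Per-organ color jitter
  (`color_spread`, default σ = 10 8-bit units) controls class
  separability: 0 gives disjoint class colors, large values force heavy
  overlap.
* **Illumination nuisances**: a global brightness factor U(0.85, 1.15) and
  elliptical cast shadows (multiplicative darkening 0.45–0.70 covering
  ~12% of the image) perturb the image only, never the mask — reproducing
  the shadow/background confusion that limits field accuracy.

Per-image seeds derive from `SeedSequence([master_seed, index])`, so
datasets are order-independent and any single image can be regenerated in
isolation.

What the generator does **not** emulate: perspective projection and depth,
specular highlights, wind blur, extraneous objects (tracks, color charts),
and within-organ senescence gradients.  Tests passing on synthetic scenes
therefore demonstrate that the implementation is correct and that the
architecture can exploit color + texture + shape cues under occlusion and
shadow; they do not certify field-level accuracy.

## Superpixel correction

`slic_segment` wraps scikit-image's CPU SLIC with the parameter contract
(S, C, N) = (superpixel size, compactness, iterations); seed centers
number (H/S)·(W/S) and small fragments are merged by the connectivity
step, so realized counts deviate from the grid count by a few percent.
Compactness is interpreted on RGB scaled to [0, 1] (no Lab conversion), so
C = 0.2 is image-independent.  Correction is whole-region assignment:
an explicit `(region_id → class)` edit list (the batch analogue of
interactive correction), or `majority_vote_cleanup`, which sets every
region to its modal predicted class (ties toward the lower class index).
Cleanup can only help where superpixels align with organ boundaries; on
scenes whose structures are thinner than the superpixel scale it can
erase them — the tests use chunky-organ scenes for the improvement check.

## LPR statistics

`compute_lpr` counts labels; images with no panicle pixels keep their
record with the ratio marked missing (NaN) rather than infinite, so
summaries stay robust (a strict mode raises instead).  Whether LPR is
computed before or after superpixel refinement is the caller's choice;
the pipeline records which mask was used.

The SSR (shortest-significant-ranges) multiple range test is implemented
as the Duncan procedure: one-way ANOVA residual mean square MS_E with
df = N − k; means ranked descending; for a span of p ranked means the
critical range is `q(1−α_p, p, df) · sqrt(MS_E / n_h)` with protection
level α_p = 1 − (1−α)^(p−1) (studentized-range quantile from SciPy) and
n_h the harmonic mean group size (for unequal groups).  A range enclosed
by a non-significant range is itself declared non-significant, which makes
the non-significant pairs form rank intervals; maximal intervals become
the letters of the compact letter display.  Significance declarations are
cross-checked against a permutation oracle in the tests.

## Evaluation conventions

* mIoU averages over the 3 classes, excluding classes absent from both
  truth and prediction (per evaluation pool; pooled multi-image reports
  rarely trigger the exclusion).
* Per-class accuracy is recall `p_ii / Σ_j p_ij`; undefined (NaN) for
  classes absent from truth.
* ROC/AUC is one-vs-rest per class over pooled pixels with the class's
  softmax probability as score; ties use the midpoint (Mann–Whitney)
  convention; the macro AUC averages the defined class AUCs.  Stage-level
  AUC means pooling the pixels of that stage's images.

## Desk-scale accuracy protocol

The reference method trained for days on GPU hardware with thousands of
field patches; the package fixes a reduced protocol that runs on one CPU
in minutes (`lprseg.benchmark`): 200 generated training scenes, 20
validation scenes and 50 test scenes at 128×128 under the generator
defaults above (YG colors, σ = 10 spread, shadows on); a 16-channel,
depth-2 FPN-Mask; focal loss γ = 2 with inverse-frequency α; Adam with
batch 24 in three phases — 6 epochs at 1e-3, 4 epochs at 1e-3, 4 epochs at
3e-4 — each phase restarting the optimizer's moment estimates from the
best-by-validation weights of the previous one.  The warm restarts matter
more than the final rate drop here: resetting Adam's second moments after
the loss has collapsed restores large effective steps for the remaining
hard (boundary and shadow) pixels, and validation pixel accuracy jumps
accordingly, which a continuous run with the same total epoch count and a
step-decay schedule does not reproduce.  Evaluation pools all ~819k test
pixels.  Problem sizes were chosen as the smallest at which the experiment
comfortably clears its accuracy checks on one CPU; they are part of the
package's own protocol, not a claim of equivalence to the full-scale
study.

## Known limitations

* The NumPy network trains small models at small resolutions; it is a
  faithful but not fast substrate — no GPU, no multi-threaded convolution.
* Superpixel boundaries from scikit-image's SLIC differ numerically from
  GPU SLIC implementations with the same (S, C, N).
* LPR from a single 2-D projection ignores perspective deformation; no
  correction model is applied (none is established).
* The interactive correction step is batch-only (edit lists); there is no
  GUI.
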