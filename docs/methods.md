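# Methods

## The detection model

`teadet` builds a single-class, three-scale one-stage detector from a
declarative genotype (`ModelConfig`): stem (`focus` slicing or a single
k=6, s=2 convolution — parameter-identical by construction, since
space-to-depth turns a `(c, H, W)` input into `(4c, H/2, W/2)` before a
k=3 convolution and `4c·9 = c·36`), four backbone CSP1_n stages with
nominal repeats `(n1, n2, n3, n4)`, SPP, and a PANet or pure top-down
FPN neck feeding heads at strides 8/16/32 with `3·(num_classes+5)`
output channels each.

Two multiples set the family's scale: `depth_multiple = 0.33` maps a
nominal repeat `n` to the realised count `max(round_half_up(0.33·n), 1)`,
and `width_multiple = 0.50` halves every nominal channel width (rounded
up to a multiple of 8).  Round-half-up is load-bearing: it is the only
rounding under which the distinct nominal configurations `(8,8,3,3)`,
`(9,8,2,2)`, `(9,9,3,1)` and `(8,9,2,2)` collapse to the same effective
depths `(3,3,1,1)` and hence to bit-equal parameter counts, as the
variant tables require.

The **FPN** realisation keeps the top-down pathway (1×1 reductions,
2× nearest upsampling, merge CSP blocks at P4 and P3), removes the
bottom-up aggregation branch entirely, and retains one CSP block on the
P5 branch applied directly to the SPP output so that the three head
input widths stay (128, 256, 512).  This is the minimal neck edit
consistent with the published parameter drop of exactly 1,033,344.

**DSConv** (the quantised neck convolution) replaces each 3×3 bottleneck
convolution inside the neck CSP blocks.  The kernel is blockwise
variable-quantised — one block per (output channel, kernel row), i.e.
block length `C_in·K` — to `bits = 4` signed levels, with a learned
scale *and* shift per block (2·K parameters per output channel).
Inference is emulated in float with a straight-through estimator;
true integer kernels are a non-goal.  This bookkeeping reproduces the
published counts of both DSConv variants exactly (+3,456 over the
baseline with the PANet neck, +2,688 with FPN).

## Counting conventions

Parameter counts are reported in **deployment (BN-fused) form**: batch
normalisation folds into the preceding convolution, so each convolution
contributes `C_in·C_out·K² + C_out`.  All published variant-table counts
match this convention bit-for-bit; the all-learnables count (including
affine pairs) is exposed alongside as `parameter_count_train`.
Running statistics are never counted.

FLOPs: the headline number is conv-only `2·C_in·K²·H_out·W_out·C_out`
(one multiply-accumulate = 2 ops; bias, normalisation, activation and
pooling excluded), which yields 15.754 → printed 15.8 GFLOPs for the
baseline at 640×640.  The `(2·C_in·K²−1)` variant is available from the
same trace.  `summarize` traces shapes once at a 64-px input and scales
by the exact quadratic factor; all strides divide the input, so the
scaling is lossless.

## Frequency-domain cross-modal attention (FFA)

For feature maps `F_rgb, F_dir` (same `C×M×N`), each channel is
transformed by an unnormalised 2-D DFT.  Attention is computed on
*magnitude* spectra and applied as real multipliers to the *complex*
spectra, so phase is exactly invariant through both attention stages;
the inverse DFT's real part returns to the spatial domain (the residual
imaginary part is below 1e-6 by conjugate symmetry).

* Channel stage: global max- and mean-pooling of each stream's magnitude
  spectrum (scaled by `1/sqrt(M·N)` so pooled statistics are O(1)
  regardless of map size), concatenated to a 4C vector, passed through a
  shared two-layer perceptron (hidden `C/2`, ReLU) and a sigmoid, split
  into two C-vectors.
* Spectral stage: the two refined magnitude spectra concatenate to
  2C×M×N, pass 1×1 conv (hidden `C/2`) → ReLU → 1×1 conv → sigmoid into
  a 2-channel weight map, split into two 1×M×N maps broadcast over C.
* Re-enhancement is cross-wired: the purified D_IR map, through two 1×1
  convolutions (with normalisation + SiLU by default; a flag disables
  both for algebraically exact configurations), is added to the RGB
  input, and vice versa.

The perceptron output layers use a small-gain initialisation (×0.05) so
both attentions start near 0.5 and away from sigmoid saturation — with
unnormalised DC magnitudes of order `M·N`, a standard initialisation
saturates float32 sigmoids and destroys the (0,1) weight range.

The dual-stream detector runs two unshared improved backbones over the
RGB image and the `D_IR_IR` composite, applies one FFA block after each
pyramid-producing stage (strides 8/16/32, channels 128/256/512), and
feeds the elementwise sum of the two post-fusion streams to a single
improved neck and head.  The ablation mode (`use_ffa=False`) sums the
raw stage outputs instead.  The perceptron sizings above are this
package's choice; the dual-stream totals therefore need not match any
externally printed multimodal parameter count.

## Scale matching

Relative scale of a box is `sqrt(w·h/(W·H))` — one scalar, symmetric in
width and height.  Matching dataset 2 to dataset 1 computes the means
`s1, s2` and applies the single global factor `a21 = s1/s2` to every
object whose relative scale exceeds the judge threshold (default: the
target mean itself).  Each object is cut along its box, resampled
bilinearly (anti-aliased when shrinking), and pasted back centred on the
original box centre; the vacated ring is filled with the nearest
surrounding pre-edit pixel (`scipy.ndimage.distance_transform_edt`), so
every pixel stays defined.  Enlarged patches overwrite underlying
content and clip at image bounds.  Overlapping boxes are processed in
decreasing-area order so the smallest targets re-paste last.  Factors
that would shrink an object below 1 px clamp with a warning.

## Loss, metrics, training

`L = L_confidence + L_classification + L_box`, summed exactly in the
working precision.  Objectness targets are the detached, clipped
complete-IoU of each assigned prediction; per-level objectness balance
(4.0, 1.0, 0.4) and term gains (obj 1.0, cls 0.5, box 0.05).  Anchor
assignment uses the width/height ratio test `max(r, 1/r) < 4` against
three priors per level plus up to two nearest neighbour cells.  With one
class the classification term is identically zero.

Evaluation decodes `xy = (2σ−0.5+grid)·stride`, `wh = (2σ)²·anchor`,
applies class-agnostic NMS (IoU 0.45), matches greedily in descending
confidence, and integrates the all-point precision envelope over
recall.  `mAP95` defaults to the IoU 0.50:0.95 average — the convention
whose magnitudes (~0.43 for 30-px objects) match published practice —
while the literal single-threshold IoU=0.95 value, near zero for such
small objects, is reported as `map95_strict`.  TP/FP/FN counts use a
0.25 confidence floor.

Training follows the published recipe: SGD, momentum warm-up 0.8→0.937
over three epochs, cosine learning rate 1e-2→1e-5, weight decay 5e-3
(as printed, although ten times the usual codebase default — possibly a
typo there; configurable here), batch 4, online horizontal flip, random
rotation, colour gain and mosaic, each toggleable.  The lowest-loss
weights are retained.

## Synthetic scenes

The generator emulates the target corpus's statistical structure, not
its appearance: a low-frequency green background; 200–400 anti-aliased
two-lobe strokes (bud + leaf) per 512×360 frame with random pose, a
lognormal relative-scale distribution (median 0.035, σ=0.30, so ~90% of
objects fall below 0.05), and a configurable colour offset Δ (Δ=0 makes
objects chromatically invisible — the hard multimodal case).  The same
alpha mask drives all three modalities: depth is a smooth 0.5–1.0 m
plane with objects ~6 cm nearer, stored 8-bit over a 2 m full scale,
with zero-valued void blobs at a configured rate; IR is a reflectance
field brightened under objects with multiplicative log-normal speckle,
stored 16-bit.  Boxes are tight to the rendered support and always pass
the >2×2 px annotation filter.  Generation is bit-reproducible per
seed.

What passing tests on these scenes do *not* show: robustness to real
sensor physics (TOF flying pixels, motion, illumination), to occlusion
statistics of real canopies, or detection accuracy at field scale —
the published mAP values require the original (unreleased) field corpus
and full-scale training and are out of scope here.

## Desk-scale problem sizes

The test suite exercises training at reduced sizes chosen so the whole
suite runs on one CPU: the overfit smoke test trains the improved
preset on 8 synthetic 96-px frames for 100 iterations (batch 4) and
requires the total loss to at least halve; the transfer check trains on
a scale-matched source (mean scale 0.08 → 0.04) for 180 iterations at
128 px and compares first-iteration validation box loss against random
initialisation over 5 seeds (≥4/5 must favour the warm start).  At
64 px the 0.04-scale objects fall below what the default anchors can
match, which is why these tests run at 96–128 px.

## Known limitations

* DSConv is float-emulated; no integer kernels.
* The FFA perceptron sizes are package choices (the operator is
  otherwise fully specified); dual-stream parameter totals are
  reported but have no external reference value.
* GFLOPs of the DSConv variants count the float-equivalent
  convolutions; a cost model for quantised arithmetic is not attempted.
* The rotation augmentation remaps boxes by enclosing rotated corners,
  which inflates elongated boxes slightly at large angles.
* The 75%-occlusion annotation rule of the motivating corpus is a human
  labelling criterion; it is documented, not enforced.
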