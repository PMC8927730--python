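# Methods

## Problem setting

Light-trap monitoring photographs insects attracted to a lamp onto a bright
board. The resulting detection problem has three hard properties: objects
are very small (a typical pest bounding box covers on the order of 1.6% of
the area of an ordinary "general object" box), the size spread across
species is wide (roughly a 32-fold ratio in mean box area between the
largest and smallest classes), and several species are near look-alikes.
`trapdet` implements a minimal two-stage detector whose two distinctive
components target exactly these properties: a three-stage
feature-enhancement neck and a distance-penalized overlap score (Soft-IoU)
used for label assignment and duplicate removal.

## The enhancement neck

The backbone exposes four feature levels at strides 4, 8, 16, 32 (grids
follow `ceil(size/stride)`). The neck transforms these in three stages,
all built from 1x1/3x3 convolutions and bilinear resampling so the whole
module is differentiable end-to-end and size-agnostic.

**1. Super-resolution pyramid expansion.** Each backbone level is first
projected to a common width `C` (default 256) by a 1x1 convolution. A
finer stride-2 level is synthesized from the stride-4 lateral by a
transposed convolution (kernel 4, stride 2, padding 1 — exactly doubling
the grid; for odd image sizes the output is cropped to the ceil-division
grid). Top-down fusion then adds each level, bilinearly resized, into the
level below across the five finest levels, and each fused level passes a
3x3 smoothing convolution. Finally a stride-64 level is appended by
stride-2 subsampling (max pooling with kernel 1) of the stride-32 output.
Result: six levels at strides 2..64. For an 800x1088 input the grids are
400x544, 200x272, 100x136, 50x68, 25x34 and 13x17.

**2. Feature full fusion.** Every one of the six levels is bilinearly
resized to each of the five stride-4..64 target grids; the six same-size
maps are concatenated (6C channels), projected back to C channels by a 1x1
convolution, and added residually to the original level of that size. The
projection is evaluated blockwise (one GEMM per source level) so the 6C
concatenation is never materialized; the learnable weight still has the
full 6C input width. Unlike adjacent-level fusion, every output level sees
every scale at once while remaining translation-equivariant.

**3. Feature full weighting.** Each level `X` is re-weighted along
position and channel:

    W(X) = alpha * pi_L(X) g(X) + (1 - alpha) * pi_C(X) X

The local term scores each position by its affinity to all other
positions, `pi_L(x_i) = mean_{j != i} <theta_L(x_j), phi_L(x_i)>`, and
scales the value projection `g(x_i)` by that scalar — a non-local block
reduced to a per-position gate. Because `theta_L` is linear, the excluded-
self sum is `S - theta_L(x_i)` with `S` the sum over all positions, so the
term costs O(N·C) rather than the O(N^2) of the defining double sum; the
test suite checks equality against the explicit double loop on all grids
up to 8x8. The channel term pools globally and rectifies,
`pi_C(X) = ReLU(theta_C(avg(X))) + ReLU(phi_C(max(X)))` — an
average-plus-max squeeze-excitation without a squashing gate.

### Choices made where the design was open

* **alpha** defaults to 0.5 (symmetric mixing of the two terms) and can be
  made a learnable scalar (sigmoid-squashed) by configuration.
* **Affinity normalization.** The raw affinity sum grows linearly with the
  number of positions, which would make the local term scale with pyramid
  level; dividing by `N - 1` (a mean over the excluded-self positions)
  keeps activations comparable across levels. A `none` mode preserves the
  raw sum.
* **Channel gate.** The rectified sum is used literally (non-negative,
  unbounded) by default so unit tests match the formula; a sigmoid gate is
  available behind a flag for training stability.
* **Weighting initialization.** The five weighting maps start
  near-neutral: `theta_L, phi_L, g` with small (sd 0.01) Gaussian weights
  so the local term begins near zero, and `theta_C, phi_C` with small
  weights and bias 0.5 so the channel weights begin at 1. The stage is
  then approximately `(1 - alpha) * X` at initialization and learns how
  far to depart from identity. Without this the unbounded products destroy
  the activation scale at random initialization and training diverges.
* **Fusion initialization.** The residual fusion projections start at
  zero, so full fusion is exactly the identity on the stride-4..64 levels
  at initialization (this is also an exact test) and the network learns
  how much cross-scale mixing to add.
* **Resampling semantics.** All bilinear resizes use half-pixel-center
  sampling, consistent between the x2 top-down upsampling and the
  arbitrary-size fusion resizes.
* **Weight sharing.** One set of weighting parameters is shared across the
  five pyramid levels (the maps are size-agnostic 1x1 projections), and
  the weighting stage is applied to all five levels.
* **Residual target.** The fusion residual adds to the post-smoothing
  levels of the expansion stage.

## Soft-IoU

Plain IoU cannot distinguish two candidates with equal overlap but
different center alignment. Soft-IoU multiplies IoU by a center-distance
penalty and a phase factor:

    SI(A, B) = beta * (1 - E(A_c, B_c) / max(diag_A, diag_B)) * IoU(A, B)

with `E` the Euclidean center distance and `diag` the box diagonal. The
bracketed penalty is read as ordinary parentheses (a ceiling would
collapse it to the constant 1 for every overlapping pair, defeating its
purpose). For stability the result is clamped two-sidedly into
`[(1 - c) IoU, (1 + c) IoU]` with `c = 0.1`, applied to the full
beta-scaled product; SI is exactly 0 whenever IoU is 0. During training
`beta = 0.9`: candidates are scored against the usual 0.5 positive
threshold, so an overlapping but badly centered candidate (e.g. IoU 0.55
with a large center offset) falls below the cut that plain IoU would
clear — only well-centered candidates train the heads. At test time
`beta = 1.1` and SI is the overlap measure in non-maximum suppression, so
near-duplicates whose centers diverge are more likely to be kept as
separate detections. Degenerate boxes (zero width or height) are rejected
rather than silently producing NaN in the diagonal ratio.

## Detector

The surrounding two-stage pipeline is deliberately standard: per-level
anchors centered on feature cells (one size per level, a multiple of the
stride, shared aspect ratios); a shared RPN head (3x3 conv + 1x1
objectness and delta heads); proposal selection by decode, clip, NMS and
top-k (at most 1,000 proposals forwarded); RoIAlign (bilinear,
quantization-free, one sample per bin center, level chosen by the
size-based heuristic); and a two-layer MLP head with (K+1)-way
classification and class-agnostic box regression in the usual
`(dx, dy, dw, dh)` log-space parameterization. Assignment uses Soft-IoU
with positive/negative thresholds of 0.5, plus the per-truth argmax rescue
so every object trains at least one candidate; an `assign_score=iou`
switch reproduces hard-IoU assignment exactly for ablations. Training is
per-image SGD (momentum 0.9) with 256-sample 1:1 mini-batches, L1
regression loss in the RPN, SmoothL1 (transition 1.0) in the R-CNN head,
cross-entropy for both classifications, and the classification/regression
layers initialized from a mean-0, sd-0.01 Gaussian. The default schedule
is 12 epochs at lr 0.0025 with a tenfold drop after epoch 8; desk-scale
profiles override iterations and learning rate.

The whole network runs on a small reverse-mode autodiff core
(`trapdet.nn`) over numpy arrays: convolutions are evaluated as one GEMM
per kernel tap over shifted strided views (no im2col buffer), and every
operation's gradient is finite-difference-checked in the test suite.
Computation is float32; box geometry and metrics are float64.

## Evaluation

Greedy one-to-one matching (highest score first, same class only, each
ground truth matched at most once) and 101-point interpolated AP. The
summary AP averages thresholds {0.50, 0.75, 0.95} in `triple` mode — a sparse summary over
loose, strict and very strict matching — or the conventional
{0.50..0.95 step 0.05} in `coco` mode; both are shipped because the two
conventions differ and published comparisons typically use the latter. `mRecall` is defined here as the mean over classes of the
maximum recall reached at IoU 0.5. Classes with zero ground truths are
excluded from all means. An independently written brute-force evaluator in
the tests (explicit per-threshold matching, direct 101-point scan) agrees
with the fast path to 1e-6.

## Synthetic scenes

The generator renders striped, rotated ellipses ("pests") on a bright,
lightly textured board and emits COCO-format annotations. Its defaults
encode the study conditions: mean box area 1.58% of a reference
general-object box (taken as 38% of the image area — a stated constant,
since only the ratio semantics matter), class mean areas log-spaced with a
32x largest-to-smallest ratio, 3-12 objects per image, and optional
near-duplicate class pairs differing by a small epsilon in stripe
frequency. A mist degradation (Gaussian blur plus contrast loss toward the
mean; sigma 0 is the identity) emulates condensation on the camera.
Annotations use the analytic tight bounding box of each ellipse, which the
rendering realizes to sub-pixel accuracy. What the generator does *not*
emulate: real insect texture and pose variation, occlusion and clutter
from wings/debris, illumination extremes, and the long-tailed class
frequencies of field data — so passing tests demonstrate the correctness
and trainability of the pipeline, not field accuracy.

## Problem sizes and tolerances

The test suite runs everything at desk scale as the package's own working
sizes: unit tests use 64-128 px images and 8-32 channel networks; the
printed-resolution check runs the full 256-channel neck once on an
800x1088 input; the end-to-end check trains 200 per-image SGD iterations
(lr 0.02, a desk-profile override of the long-schedule default) on five
256x320 scenes with three classes and recovers them at AP50 >= 0.85.
Numerical tolerances: oracle equivalences at 1e-5 (float32 forward),
evaluator cross-checks at 1e-6 (float64), exact equality where the claim
is structural (residual identity, alpha limits, ablation assignment).

## Known limitations

* Per-image (batch-1) training only; no batch normalization or
  distributed training.
* The tiny default backbone is trained from scratch; no pretrained
  weights are bundled, so absolute accuracy on real imagery is out of
  scope. Any 4-stage extractor honoring the pyramid contract can be
  plugged in.
* RoIAlign samples one point per bin; boxes smaller than a feature cell
  rely on the stride-2-derived fine levels for signal.
* The CPU implementation is practical up to roughly megapixel inputs and
  desk-scale training runs; it is not a GPU training framework.
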