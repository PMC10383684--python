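# Methods

## Problem setting

Young tea shoots ("tea buds") are small, densely packed, and nearly the same
green as the surrounding canopy, which makes them a hard single-class
detection target. The package implements the full desk-scale machinery for
this problem: a family of single-stage anchor-free detectors built from
three architectural toggles, the classical image-enhancement pipeline used
for dataset expansion, the training losses and label assignment, detection
metrics, and a synthetic scene generator that emulates the structure of
field imagery.

## Detector family

The baseline is a YOLOv8s-scale network: width multiplier 0.50, depth
multiplier 0.33 (backbone channels 32/64/128/256/512, C2f depths 1/2/2/1),
a 3x3 stride-2 stem, an SPPF tail, a PAN-FPN neck whose up-sampling paths
carry no extra convolutions, and a decoupled anchor-free head at strides
8/16/32. Box regression is distributional: each of the four box distances
is a softmax over `reg_max = 16` bins whose expectation, scaled by the
stride, gives the distance from the anchor-cell center. With one class, the
head emits 4x16 + 1 = 65 channels per scale.

Three independent modifications define eight variants:

* **C2f_DCN** (`use_dcn`): the last three backbone C2f blocks replace both
  3x3 convolutions in each bottleneck with modulated deformable convolution
  (DCNv2). A sibling 3x3 convolution predicts 18 offset and 9 mask channels;
  sampling is bilinear with zero padding outside the image, and masks pass
  through a sigmoid. The offset/mask branch is zero-initialized with the
  mask logits biased to +12 (sigmoid within 6e-6 of 1), so an untrained
  C2f_DCN reproduces plain C2f — this keeps short training runs stable and
  makes the degenerate-equivalence tests exact to float precision.
* **GAM** (`use_gam`): a global attention block after each of those three
  stages (128/256/512 channels). The channel gate permutes channels last and
  applies a two-layer perceptron C -> C/r -> C pointwise; the spatial gate is
  two 7x7 convolutions C -> C/r -> C with batch norm; both gates are sigmoids
  applied multiplicatively, and no pooling is used anywhere. The reduction
  ratio r = 4 and the insertion points are chosen so that the three
  insertions add 0.41 + 1.64 + 6.56 = 8.61 M parameters, matching the
  published +8.6 M for this modification.
* **SPPFCSPC** (`use_sppfcspc`): the SPPF tail is replaced by a CSP-wrapped
  pooling block: one 1x1 branch, and a second branch of 1x1 -> 3x3 -> 1x1
  convolutions, a cascade of three 5x5 stride-1 max pools concatenated with
  their input, then 1x1 -> 3x3 convolutions; the two branches are fused by a
  final 1x1 convolution (seven convolutions in total). Three chained 5x5
  stride-1 pools are exactly equivalent to parallel 5/9/13 kernels, which the
  tests verify. The hidden width is 512 at the 512-channel tail, chosen
  because the implied +6.4 M over SPPF matches the published variant total.

Parameter accounting is the package's primary quantitative claim: every
variant's total is checked against an independent per-layer analytic
formula, and the five headline totals (11.1, 11.4, 17.6, 19.7, 26.5 M;
+15.4 M for the full model) are recomputed from scratch by
`scripts/acceptance.py`.

### Numerical core

No GPU tensor library is assumed: the blocks run on an in-repo numpy
autodiff core (`teadetect.nn`) with hand-written vector-Jacobian products
for convolution (im2col/col2im), max pooling (argmax routing), nearest
up-sampling, indexed gathers (for the deformable sampler) and the usual
pointwise ops. Gradients of every primitive are verified against central
finite differences. Arithmetic is float32; batch norm uses eps 1e-3 and
momentum 0.03 on running statistics.

## Losses and assignment

* **Varifocal loss** on classification: positives weighted by the target
  score q, `-q(q log p + (1-q) log(1-p))`; negatives focally down-weighted,
  `-alpha p^gamma log(1-p)` with alpha = 0.75, gamma = 2. Natural logs;
  probabilities clamped at 1e-7.
* **Distribution focal loss** on the per-side distance bins: cross entropy
  against the two integer bins bracketing the continuous target, with
  weights `(y_{i+1} - y)` and `(y - y_i)`.
* **CIoU** box loss `1 - CIoU`, `CIoU = IoU - rho^2/c^2 - alpha v` with the
  aspect-ratio penalty `v = (4/pi^2)(arctan(w_gt/h_gt) - arctan(w/h))^2`
  and `alpha = v/((1 - IoU) + v)` treated as a constant in the backward
  pass, the usual convention.
* **Task-aligned assignment**: alignment `t = s^0.5 * u^6` (product form);
  per ground-truth box, the top-10 anchors by t among those whose cell
  center lies inside the box; ties broken by higher IoU then lower anchor
  index; an anchor claimed by several boxes serves the one it overlaps
  most. The varifocal target for a positive is t normalized per ground
  truth to that box's best IoU (per-box rather than global normalization —
  a deliberate choice, exposed in `LossConfig`).
* Loss gains 7.5 (box), 0.5 (cls), 1.5 (dfl) — the standard defaults for
  this detector family, exposed in configuration.

`train_smoke` is a sanity harness, not a training recipe: seeded SGD
(lr 0.01, momentum 0.937, weight decay 5e-4 on weight matrices only) on
letterboxed synthetic scenes. The suite trains at 64x64 input with batches
of 4 from 8 scenes — sizes chosen so a pure-numpy backward pass remains
comfortable on one CPU — and checks that 200 steps strictly decrease the
mean loss (first 10 vs last 10 steps). That demonstrates that gradients are
correct and the optimization loop is wired properly; it says nothing about
detection quality on real imagery.

## Image enhancement

Histogram equalization operates on the luminance plane only: RGB is
converted to YCbCr (BT.601 full range), Y is remapped by
`k -> round(S_k * 255)` with S_k the cumulative histogram fraction, and the
chroma planes are untouched. The gamma transform `y = c x^gamma` operates
on [0, 1]-normalized intensities with clipping (c defaults to 1.3; applied
to raw 8-bit values it would overflow, so normalization is the only
sensible reading). Homomorphic filtering takes log(1 + x) per channel,
multiplies the centered 2-D spectrum by the Gaussian high-pass transfer
`H = (gh - gl)(1 - exp(-c D^2 / D0^2)) + gl`, inverts, applies expm1, and
min-max rescales each channel to [0, 255]. Defaults gl = 0.5, gh = 2.0,
c = 1, D0 = 30 cycles. The local variant partitions the image into an
n x n grid of contiguous sub-images (the last row/column absorbing the
remainder) and filters each independently.

Quality is scored by local average entropy: Shannon entropy of the 256-bin
histogram per block and channel, averaged over the grid and over R, G, B.
On a scene with a strong illumination gradient, local filtering raises this
score while global filtering lowers it (each block's histogram is
re-stretched locally, whereas the global exponential maps most pixels into
a few low levels) — the qualitative ordering the enhancement pipeline
exists to produce, and the one the acceptance suite asserts.

## Synthetic scenes

`synth_scene` draws a dark textured canopy (low-frequency color patches
plus per-pixel noise around RGB (30, 64, 32)), scatters 8-16 buds per
640-px image (roughly the density of the field dataset the generator
emulates), and multiplies in a smooth linear illumination ramp of ±55%
along a random direction. Each bud is a pair of overlapping rotated
ellipses — a shoot (semi-axes L x 0.35-0.5 L, L in 14-30 px) and a leaf
lobe — in bright green around RGB (96, 168, 64); the recorded box is the
tight bound of the drawn mask, and by construction at least 60% of every
box is bud pixels. A 15% occlusion probability places some buds adjacent to
their predecessor. Everything is determined by the seed.

What the generator does *not* model: real leaf texture and venation, specular
highlights, depth-of-field blur, perspective scaling, and the color
ambiguity of mature leaves. Tests passing on these scenes validate the
pipeline's mechanics (geometry, losses, metrics, enhancement ordering), not
field accuracy; published mAP/recall values on real tea imagery are
explicitly out of scope.

## Design choices where the design was open

* The printed transfer-function exponent for homomorphic filtering diverges
  as written; the standard Gaussian high-pass form with a negative exponent
  is implemented, consistent with its stated low/high-frequency limits.
* "n x n sub-images" is read as an n-by-n *grid* (block size shrinking as n
  grows), consistent with entropy increasing with n.
* The alignment metric is implemented as the product `s^alpha u^beta`
  (its printed form shows a sum, but the accompanying text describes a
  product, and only the product annihilates at u = 0).
* The head is anchor-free; assigner constants (alpha 0.5, beta 6, top-10),
  loss gains and the varifocal constants are the standard defaults of this
  detector family, exposed in configuration rather than hard-coded.
* AP uses 101-point interpolation for both AP50 and AP[50:95]; matching is
  greedy one-to-one by descending score, a ground truth never matched twice.
* VOC files are 1-based inclusive on disk, 0-based half-open in memory;
  mosaic fragments under 2 px on either side are discarded.
* A mixup probability appears among the training hyperparameters carried in
  `ModelSpec` but is inert: no mixup procedure is defined for this
  pipeline, so it is recorded as configuration only.

## Known limitations

* The numpy core is single-threaded desk-scale; full 640-px training is out
  of reach and out of scope.
* Multi-class support is nominal (nc is configurable but the loss path is
  exercised single-class, matching the one-class problem).
* The published per-variant layer counts use an unstated enumeration
  convention and are not reproduced; inference times and GFLOPs are
  hardware- and profiler-dependent and likewise out of scope.
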