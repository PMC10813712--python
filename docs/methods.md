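# Methods

## The model

RGGC-UNet is an encoder–decoder network for two-class (background /
signet-ring-cell) semantic segmentation of 128×128×3 H&E patch images.
Its premise is that most of a UNet's convolutional work is redundant:
a **ghost block** generates half of each feature set with a 1×1 pointwise
convolution (the *intrinsic* features) and the other half by a cheap
depthwise transform of those intrinsic maps, concatenated intrinsic-first.
Because the pointwise half never sees a spatial neighbourhood, the encoder
pairs every ghost expansion with **ghost coordinate attention (GCA)**:
features are mean-pooled along width (→ C×H×1) and along height (→ C×1×W),
jointly encoded by a shared ghost block, split, and mapped by two separate
ghost blocks with sigmoids into directional attention maps in (0,1) that
multiply the expanded features (the **GGC block**).  A **RGGC block** wraps
GGC-expand → ghost-reduce into a residual unit; its stride-2 variant
performs the encoder's downsampling.

Encoder plan: stem (full resolution) → [3×3/2 max-pool + 1 RGGC] →
[2 RGGC, first stride-2] → [3 RGGC, first stride-2] → [1 stride-2 RGGC].
Decoder: four stages of 2×2/2 transposed convolution + ReLU, skip
concatenation, and a 1×1 convolution + ReLU back to the skip width; a 1×1
head plus per-pixel softmax.  Four deep-supervision heads (residual block,
two 1×1 convolutions, bilinear upsampling, softmax) are attached to the
decoder stages during training only.

## Loss

For patch label `y_p` (1 iff the ground-truth mask contains any lesion
pixel) and foreground probabilities `ŷ`:

    L_CDL = 1 − [ y_p · D(ŷ, y) + (1 − y_p) · D(1 − ŷ, 1 − y) ],
    D(p, t) = (2·Σ p·t + ε) / (Σ p + Σ t + ε),  ε = 1e-5.

Both terms are read as patch-level smoothed soft-Dice ratios (sums inside
the ratio, factor 2 in the numerator, ε in both terms); this is the only
reading under which the loss is 0 for a correct all-zero mask on a
negative patch and penalises false positives gradedly.  The total
training loss averages the CDL of the main head and the four auxiliary
heads with configurable weights (defaults: all 1, normalised by the weight
sum); auxiliary heads use the same CDL (a switch selects plain Dice).

## Numerical engine

The network runs on a compact reverse-mode autodiff engine over numpy
(`rggcunet.nn`): grouped/pointwise/depthwise convolution (im2col + BLAS or
einsum), transposed convolution with kernel = stride, batch normalisation
(biased batch variance; running statistics with momentum 0.1), 3×3/2
max-pooling, half-pixel-centre (align-corners-false) bilinear resampling,
softmax, and Adam.  Every primitive is validated against central finite
differences and, for convolution/resampling, against scipy/scikit-image
oracles in the test suite.  All computation is float32 (float64 in
oracle tests), single-threaded deterministic.

## Complexity accounting and the reference configuration

`count_macs` tallies analytic multiply-accumulates per primitive from its
shapes during one inference forward pass (convolutions, transposed
convolutions, normalisations, bilinear maps; pooling and elementwise
fusions are free).  `inspect` prints GFLOPS under both conventions in
circulation — one FLOP per MAC (the convention of the common ptflops-style
analyzers) and two FLOPs per MAC.

The architecture family fixes the block wiring but not the channel plan.
The repository's frozen reference configuration — stage widths
(744, 912, 356, 368, 1000), GGC expansion 2.4, GCA reduction 16 — was
calibrated once, by coordinate search over widths and expansion, so that
the assembled network matches the published complexity accounting for
this architecture: ≈48.03 M trainable parameters and ≈51.86 GFLOPS at
128×128×3 under the one-FLOP-per-MAC convention (both within 0.3%).  Wide
full-resolution stages carry the compute; the deep-supervision heads
contribute parameters but zero inference cost.  MACs are linear in H·W up
to the GCA branches, whose pooled 1-D encodings scale with H+W; at
doubled resolution the deviation from exact ×4 scaling is below 1%.

## Design decisions where the architecture was underdetermined

- Ghost ratio fixed at 2 with a 3×3 depthwise cheap operation; batch
  normalisation + ReLU after each sub-convolution, normalisation without
  activation in the residual-reducing ghost block (the usual ghost
  bottleneck recipe).
- Inside GCA the ghost blocks use a **1×1 cheap operation**: the attention
  transform must act per position along the pooled axis — permuting input
  rows must permute `a_h` identically — and any wider depthwise kernel
  would smear positional information across coordinates.  The shared
  block keeps normalisation + ReLU; the two sigmoid heads are plain
  convolutions (bias, no normalisation).
- The GCA branch taps the GGC block's input and emits attention at the
  expanded width, fused multiplicatively (attention semantics; the
  parallel-branch wiring that makes the product well-formed).
- Stride-2 inside RGGC: a depthwise 3×3/2 convolution between expansion
  and reduction; projection shortcut = depthwise 3×3/stride + pointwise,
  each with normalisation.
- Stem: one 3×3 convolution + BN + ReLU providing the full-resolution
  skip.  Decoder 1×1 convolutions project to the skip width; transposed
  convolutions use kernel 2, stride 2.  Two-class softmax head rather
  than a single-logit sigmoid.
- Inputs not divisible by 16 are reflect-padded and the prediction cropped
  back (`data.pad_to_multiple`, used by `predict_image`).
- GCA bottleneck: ReLU nonlinearity, reduction 16 with a floor of 8
  channels (rounded even so ghost splits stay valid).
- Optimiser: the published protocol lists Adam with "momentum 0.99 and
  weight decay 1e-8"; read as beta1 = 0.99, beta2 = 0.999, L2 weight decay
  1e-8, all exposed in the config.

## Synthetic data

Clinical SRC datasets are not redistributable, so the generator renders
what the task is morphologically about: pale mucin-filled elliptical
cells (semi-major axis 12–24 px, aspect 0.75–1, 1–4 cells per positive
128×128 patch, overlaps allowed) with a darker crescent nucleus displaced
to 0.85 of the radius, on a pink/purple stromal background with smooth
tonal variation and Gaussian pixel noise (σ = 0.02).  Masks are the exact
analytic union of the cell ellipses evaluated at pixel centres — binary
by construction.  Patch seeds fix all randomness; datasets mix 75%
lesion-free patches by default, mirroring the roughly 1:3
positive:negative composition of screening sets for this task.

What it does **not** emulate: staining variability between labs, tissue
texture and nuclear clutter of real stroma, out-of-focus regions, other
cell types with ring-like appearance, and annotation noise.  Green tests
on synthetic data therefore certify the machinery (shapes, losses,
optimisation, metrics, round trips), not clinical segmentation quality.

## Problem sizes used in tests

Unit and property tests run on small tensors (≤ 8×8 spatial) against
brute-force oracles.  The end-to-end learning check trains a narrow model
(stage widths 16–96, expansion 2.5, main-head loss only, Adam beta1 0.9)
on eight fixed-seed 128×128 synthetic patches for at most 300 Adam steps
at the protocol learning rate 1e-4 and batch size 4, and requires
training-set DSC ≥ 0.95; within the fixed step budget this short schedule
favours the plain Adam momentum over the protocol's 0.99 and concentrates
the gradient on the main head.  The complexity check builds the
full 48 M-parameter reference network and profiles one 128×128 forward
pass.

## Known limitations

- Transposed convolution supports kernel = stride only (all the decoder
  needs); odd-size upsampling paths would need extension.
- Training the reference configuration at the published protocol
  (2000 epochs) is a GPU-scale undertaking; on CPU this package trains
  small configurations for demonstration and testing.
- The MAC counter attributes zero cost to pooling, activations and
  elementwise fusions; unsupported dynamic layers would be logged and
  counted as zero.
- Batch-norm running statistics use the biased batch variance; at the
  tiny batch sizes used in tests this differs negligibly from the
  unbiased convention.
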