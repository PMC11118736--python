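# Methods

`lungfat` implements a two-stage analysis of axial chest-CT stacks:
first a recurrent classifier brackets the lung region by finding the
first and last lung-bearing slices, then a configurable multi-module
UNet segments subcutaneous (SAT) and visceral (VAT) adipose tissue on
the slices inside that range.  Because no public dataset with the
required per-slice labels and fat masks exists, a synthetic phantom
generator provides fully labelled volumes with the same statistical
structure; every training and evaluation path in the package runs
end-to-end on phantoms.

## Numerical core

No deep-learning framework is used.  `lungfat.autodiff` is a minimal
reverse-mode automatic-differentiation engine over numpy arrays with
exactly the operations the two networks need: broadcast arithmetic,
sigmoid/tanh/relu, elementwise maximum, channel concatenation,
same-padded stride-1 convolution (im2col, BLAS matmuls), 2x2 max
pooling, nearest-neighbour upsampling, global average pooling, dense
layers and a fused softmax cross-entropy.  The optimiser is stochastic
gradient descent with momentum expressed as an exponentially weighted
gradient average, v <- beta*v + (1-beta)*g, theta <- theta - lr*v,
with beta = 0.9.

Exact-value contracts (oracle comparisons, closed forms) run at the
float64 default; the training loops switch to float32 working
precision, which halves memory traffic without affecting convergence.
Inference runs in a graph-free mode so that batched prediction does
not retain backward buffers.  Weight initialization is seeded
He-style normal scaled by fan-in; biases start at zero.

## Slice localization

Slices are grouped into sliding windows of L consecutive slices
(L in {3, 5, 7}, default 5), stride 1, each labelled by its centre
slice: FIRST (0) for the first lung-bearing slice, LAST (2) for the
final one, OTHER (1) elsewhere.  End slices without a full surrounding
window are not window centres.  Two per-slice normalizations are
available: division by the fixed 4095 intensity ceiling
(*MaxIntensity*; stored values above 4095 clip to 1) and per-slice
min-max rescaling to [0, 1] (*MaxMinNorm*, the default).

The classifier is a convolutional gated recurrent unit run over the
window in both directions.  With [.,.] channel concatenation and *
a same-padded convolution:

    z_t  = sigmoid(W_z * [h_{t-1}, x_t])
    r_t  = sigmoid(W_r * [h_{t-1}, x_t])
    h~_t = tanh(W_h * [r_t . h_{t-1}, x_t])
    h_t  = (1 - z_t) . h_{t-1} + z_t . h~_t

Initial hidden states are zero in both directions.  A configuration
flag `literal_candidate` replaces the candidate activation by
tanh(sigmoid(.)), a non-standard variant bounded to (0, tanh 1) that
is retained for comparability; the standard tanh candidate is the
default.  The two final hidden states are concatenated channel-wise,
globally average pooled, and classified.

The classification head is a small two-layer perceptron
(2H -> 16 -> 3) rather than a single linear map.  This is deliberate:
after pooling, the decisive evidence is "lungs seen by the forward
sweep" and "lungs seen by the backward sweep", and the OTHER class is
their exclusive-or (lungs on both sides of the window, or on
neither).  That decision boundary is not linearly separable, and a
linear head demonstrably plateaus at majority-class accuracy; one
hidden layer is the smallest fix.

Class imbalance (OTHER windows dominate roughly 3:1) is addressed by
the logarithmic weight

    w_i = n_i / sum(n);  W_i = 1 / ln(alpha + w_i),  alpha = 1.1,

so that with two or more classes every W_i lies strictly inside
(1/ln 2.1, 1/ln 1.1) ~ (1.348, 10.49).  The natural logarithm is used
throughout.  How W enters training is configurable: `additive` (the
default) adds the true class's W to the sample's cross-entropy term as
a constant — the printed form of the weighted loss, which shifts the
reported loss but leaves gradients untouched; `multiplicative` scales
the term by W; `none` disables it.  A complementary mechanism,
`balance_subsets`, partitions the window set into disjoint subsets
with a fixed number (± tolerance) of FIRST/LAST-bearing windows each,
deterministically for a given seed, so training can run on
prevalence-balanced data.

At evaluation, each volume's predicted FIRST index is the centre index
of the window maximizing the FIRST probability (first occurrence wins
ties, i.e. the smaller index), and likewise for LAST.  Localization
error is the mean distance in millimetres,

    MD = mean(|i_pred - i_true| * spacing),

reported as the average of the FIRST-side and LAST-side values.  The
absolute value keeps MD non-negative; MD = 0 iff every prediction is
exact.

## Segmentation

The backbone is a 2-D UNet: `depth` encoder levels (default 4) of two
3x3 convolutions + relu, 2x2 max-pooling between levels, channel
widths base*2^i (base 16 by default), a bottleneck, and a symmetric
decoder using nearest-neighbour upsampling followed by a 1x1
projection.  Input sides must be divisible by 2^depth.  The final 1x1
convolution passes through the logistic function sigma(p) =
1/(1+e^{-p}), giving a per-pixel probability in (0, 1); masks are
binarized at 0.5 for metric computation.

Three optional blocks modify the skip pathway, independently
switchable (8 combinations):

* **multi-resolution (MR)** — the next deeper encoder level's features
  are upsampled, 1x1-projected to the skip's width and added to the
  skip (adjacent-pair fusion; wider fans are a possible extension);
* **attention gate (ATTN)** — additive attention
  alpha = sigmoid(psi(relu(W_s*skip + W_g*up))), computed against the
  upsampled decoder features of the peer level, rescales the skip;
  |output| <= |skip| elementwise since alpha in (0, 1);
* **competitive (CP)** — a two-piece Maxout: the elementwise maximum
  of the pathway and the 1x1-projected upsampled decoder features.
  Standalone CP (no MR) compares the raw skip against that projection,
  the only available peer pair.

When several blocks are enabled they compose MR -> ATTN -> CP, so the
Maxout always arbitrates the final two candidates.  The result is
concatenated with the upsampled decoder features exactly as in a plain
UNet.

Training minimizes the smoothed Dice complement

    DC  = (kappa + 2*sum(y.p)) / (kappa + sum(y.y) + sum(p.p)),
    DCL = 1 - DC,   kappa = 1,

with the squared-sum denominator (identical to the count form on
binary masks).  kappa makes the empty-vs-empty case well defined
(DC = 1).  The optional class weight W is *added* to the loss
(DCL_W = DCL + W): it is a constant per sample and does not alter
gradients; it is kept because it is the printed form of the weighted
loss and is toggleable via `use_weight_penalty`.

Evaluation reports smoothed Dice, precision TP/(TP+FP), recall
TP/(TP+FN) and their harmonic mean F1, computed per image on
0.5-binarized maps and averaged over the set (not pixel-pooled).
Degenerate denominators yield 0 with a logged warning so batch
evaluation never aborts.  Because it is ambiguous whether a given
evaluation protocol smooths the Dice at test time, the harness reports
both the binarized smoothed Dice and the soft (probability-map) Dice.
Cross-validation summaries use the sample standard deviation and are
formatted "mean ± sd" on the percent scale to one decimal.

## Phantom generator

Each volume stacks `n_slices` axial slices of one synthetic subject:
an elliptical body (soft tissue) with per-volume jittered axes, a
subcutaneous fat ring just inside the body contour whose thickness
varies smoothly around the perimeter, two elliptical lungs that appear
at `lung_first`, grow then shrink unimodally, and vanish after
`lung_last`, and 2-6 irregular (angularly perturbed elliptical) VAT
blobs around the mediastinum on lung-bearing slices.  SAT and VAT are
disjoint by construction and VAT excludes lung interiors.

Intensity bands on the [0, 4095] scale: background 0-100, lung
interior 100-400, fat 1400-1800, soft tissue 2200-2800, with additive
Gaussian noise (sd 50 by default) and quantization to 16-bit integers
clipped at 4095.  The bands mimic CT ordering (air < fat < soft
tissue) and are exactly disjoint at zero noise; absolute values are
arbitrary since both normalizations are scale-free.  One integer seed
drives a single pseudo-random stream per volume; no global state.

Defaults: 12 slices, 2.5 mm spacing, 64x64 pixels for desk-scale work
(512x512 is supported; localization experiments in the tests and the
acceptance script use 32x32 windows to keep CPU runtimes in minutes —
sizes are stated with every reported number).

What the phantoms do *not* emulate: ribs, vessels, pathology, partial
volume effects, scanner noise texture, anatomical variability beyond
affine jitter, or DeepLesion's +32768 stored-intensity offset (the
reader applies no offset; callers using real DeepLesion PNGs must
handle it upstream).  Passing phantom tests therefore demonstrates
correctness of the algorithms and the trainability of the
architectures on class-topology-faithful data — not clinical
performance.

## On-disk formats

Slices are single-channel 16-bit PNGs read back exactly as stored.
Masks are JSON documents `{"tissue": "SAT"|"VAT", "polygons":
[[[x, y], ...], ...]}` whose vertices are integer pixel-corner
coordinates (pixel (r, c) spans corners (c, r)-(c+1, r+1)); a pixel
belongs to the mask when its centre has an odd winding count over all
polygons (even-odd rule).  Pixel centres sit at half-integers and can
never lie on a polygon edge, so rasterization is unambiguous, holes
are represented naturally as inner rings, and the phantom exporter
(which traces masks as unions of pixel squares via polygon geometry)
round-trips masks *exactly*.  Localization labels are one CSV per
volume (`index,label`, label in {0, 1, 2}).

## Degenerate inputs and numerical choices

* Constant slices make min-max normalization undefined: a
  degenerate-input error names the slice index.
* MaxIntensity clips stored values above 4095 (legal in 16-bit files)
  to 1.0 to keep the output range contract.
* Maxout gradient ties go to the first candidate; pooling ties to the
  first occurrence.
* Inverted localization ranges (predicted first > last) are swapped
  with a logged warning; the selected range is always ordered.
* Logistic outputs are clipped to [1e-12, 1-1e-12] in probability maps
  so the open-interval contract survives float saturation.

## Problem sizes used by the test suite and acceptance script

Segmentation convergence runs a base-16, depth-4 MR+ATTN UNet on 20
SAT phantom slices at 64x64 (about two minutes of CPU).  Localization
recovery trains an 8-channel, kernel-3 ConvBiGRU on the 5-slice
windows of 30 phantom volumes at 32x32 and evaluates mean distance on
10 held-out volumes.  The end-to-end smoke run uses 5 volumes.  The
ablation harness sweeps all 8 module combinations and emits a
cross-validated metrics table; no ordering among the combinations is
asserted on phantoms, where the blocks' relative merits need not match
their behaviour on clinical data.

## Known limitations

* The engine is CPU-only and unoptimized beyond BLAS-shaped matmuls;
  512x512 training is possible but slow.
* Localization windows score each centre independently; no sequence-
  level decoding (e.g. enforcing exactly one FIRST before one LAST)
  is applied beyond the argmax-and-order rule.
* The additive class-weight penalty is gradient-free by construction;
  counteracting imbalance during optimisation requires the
  multiplicative mode or subset balancing.
* Four-fold cross-validation is provided as a harness; fold statistics
  on phantoms say nothing about clinical variability.
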