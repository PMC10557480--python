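# Methods

## Model

The backbone is MobileNetV2: a 3×3 stride-2 stem to 32 channels, seven
bottleneck stages with output widths (16, 24, 32, 64, 96, 160, 320) and
strides (1, 2, 2, 2, 1, 2, 1), a 1×1 head to 1280 channels, global average
pooling, and a linear classifier.  Standard stages use inverted residuals
(1×1 expand ×t + BN + ReLU6 → 3×3 depthwise, padding 1 + BN + ReLU6 → 1×1
project + BN, skip added when stride 1 and widths match).

Any subset of stages B4–B7 can be built as `Bottleneck_RepMLP` instead:

1. 1×1 conv reducing the incoming width C to m = C/r (+BN+Hardswish),
2. a RepMLP block at width m on the incoming resolution,
3. a 2×2 stride-2 average pool when the stage downsamples (the partition FC
   cannot stride, so the RepMLP runs at the pre-pool resolution and the pool
   follows it),
4. 1×1 conv restoring the stage width (+BN), skip connection when
   shape-compatible, ECA after the block when enabled.

Each RepMLP stage is a **single block**.  The stage-level channel and
resolution bookkeeping (widths 96/160/320 at 14×14 → 7×7) is unchanged from
the backbone table; only the repeat count inside replaced stages collapses to
one.  This is the configuration whose parameter totals reproduce the
published model sizes; with per-stage repeats the pointwise convolutions
alone would already exceed them.

### RepMLP internals

For a block of width m on an S×S map, the partition side h is the largest
divisor of S not exceeding 7 — so 14×14 maps give four 7×7 partitions and
7×7 maps one.  The shipped internals, fixed once for all variants:

* **partition perceptron**: grouped FC with g = m (one (h·w)² weight matrix
  per channel), no bias, then BN over the m output channels;
* **local perceptron**: depthwise (g = m) conv branches with kernel sizes
  {1, 3, 5}, padding (K−1)/2, each followed by BN;
* **global perceptron**: per-partition GAP → FC(m → m/4) → ReLU → FC(m/4 → m),
  both with bias, added back to the partition (reduction ρ = 4).

The partition FC and the local convolutions must share the group count;
otherwise the deployment fold would coarsen the FC's block structure and
change the parameter count.  With g = m the fold is structure-preserving, and
converting a model moves its total by only 42m per block (the folded BN
parameters), invisible at the 2-decimal million scale.

These internals were selected by an exhaustive grid search over group
counts, reduction factors and pooling placements, constrained to reproduce
the published totals of the model family — 0.91 M for the default 224×224
model, 0.55 M and 0.69 M for the small-image study variants — simultaneously.
A key consequence of the partition FC is that **model size depends on input
resolution** ((h·w)² weights per channel), which is exactly what reconciles
those published totals: they are only mutually consistent when the 10-class
study variants are profiled at their native small-image input.

### Small-image variants

`make_variant(...)` with a 10-class head builds the study configuration used
on 32×32-class benchmarks: input 40×40 (images zero-padded to 40) and a
stride-1 stem, the standard small-image adaptation.  Feature maps then run
20 → 10 → 5 → 5 → 5 → 3 → 3 (stage outputs), with partition sides 5, 5, 5, 2
in B4–B7.  Two published figures in the family are *not* reproducible under
any internals consistent with the rest (the one-stage variant's 1.7 M, and
the r = 2 variant's 0.81 M — the unchanged stages alone exceed the former);
the package reproduces their orderings (0.55 < 0.72 < 1.01 < 1.79 < 2.24 and
0.69 < 0.72 < 0.78) and documents the totals it actually computes.

## Counting convention

One pinned convention serves all comparisons (`profiling`): a conv/linear
multiply-accumulate is 1 FLOP (+1/element for bias); inference BN is
2 ops/element; activations 1 op/element; average pooling k² ops per output
element; residual and branch additions 1 op/element; sigmoid 4 ops/element.
MAdd counts multiplies and adds separately (2·MAC − 1 per conv/linear output
element; elementwise ops as in FLOPs).  Under this convention the 25-class
MobileNetV2 baseline at 224×224 costs 319.3 M FLOPs and 612 M MAdd.
"Param/M" in all tables means millions of parameters.  The improved model's
FLOP total under this convention (192.5 M) is *lower* than its published
counterpart (266.7 M): the single-block RepMLP stages that match the
parameter budget are also cheaper in operations; the parameter totals, not
the operation counts, are the calibrated quantities.

## Re-parameterization

At inference the RepMLP block is affine in its input: BN₃(FC₃(x)) +
Σ_K BN_K(conv_K(x)) with all BNs frozen.  The converter (float64 throughout)
folds each branch BN into its conv (W′ = γW/√(σ²+ε), b′ = β + γ(b−μ)/√(σ²+ε)),
converts each conv to its FC equivalent by probing with the identity basis of
a partition (exact by construction), folds BN₃ into FC₃ as a row scale and
bias, and sums.  Equivalence is enforced by test at 1e-5 max-abs for blocks
and 1e-4 for whole-model logits; single-layer fusions hold to 1e-6.

## Training

Momentum SGD (momentum 0.9, weight decay 4e-5 — unspecified in the reference
configuration; these are the field's defaults) on cross-entropy without label
smoothing, learning rate cosine-annealed per epoch from lr_max to lr_min
(T = total epochs, so lr(0) = lr_max and lr(T) = lr_min).  The reference
configuration is batch 64, 30 epochs, lr 0.1 → 0.0001.  Recall/precision are
macro-averaged — micro averaging would collapse onto accuracy, and the
reported per-model values are distinct.

Desk-scale runs use `smoke_config()`: batch 16, 5 epochs, lr 0.02 → 0.0001 at
64×64 input.  The smaller batch gives a 160-image training split 50 update
steps; the lower peak rate keeps momentum SGD stable at that batch size.
Inputs are standardized by train-split channel statistics.  Two further
numerical choices matter for trainability from scratch: residual blocks
zero-initialise their final BN scale (each block starts as the identity, so
the 50-layer stack optimises like a shallow one), and all other weights are
Kaiming-uniform from the model seed.  BN uses batch statistics when training
(momentum 0.1 running updates, ε = 1e-5) and running statistics at inference
— a requirement for the deployment fold to be exact.

## Synthetic data

The generator emulates controlled-condition leaf photographs: one elliptical
leaf (randomised pose, per-crop hue, radial shading, a vein line) on a plain
background, with class-parameterised elliptical lesions (colour, count,
size, aspect, soft edges) and mild pixel noise.  The default label space is
5 crops × 5 health states = 25 classes; diseased classes also shift the leaf
hue toward chlorosis with disease severity.  Classes are constructed to be
separable from colour statistics — a raw-pixel linear probe beats 3× chance
on the 25-class set — so downstream training tests measure the pipeline, not
the dataset's difficulty.  What passing smoke tests therefore shows is that
the architecture, gradients, schedule and metrics work end to end; it says
nothing about accuracy on real field images, where backgrounds, occlusion
and illumination dominate.

Augmentation ops (flip, mirror, quarter-turn rotation, brightness, contrast,
Gaussian noise) are deterministic given their recorded seeds.  Splitting is
stratified per class (a class with fewer than two originals goes entirely to
train, with a warning).  Balancing pads each class's split to a target with
augmented copies of originals from the *same* split — leakage-free by
construction and enforced by test — and subsamples classes already above
target (augmented records dropped first).  The published 25-class per-class
table ships with the package (`PLANTVILLAGE_TABLE`); balancing a 4:1 split of
its original counts to its per-class training targets reproduces the
published 37,572-record training set.  Whether the published test counts
were themselves augmented is not documented for the source data; the
balancer supports expanding either split, applied after the split so the
leakage rule always holds.

## Limitations

* Parameter totals are exact; the improved model's FLOP/MAdd totals are not
  calibrated (see above).
* Full-scale training accuracies (tens of epochs on the real datasets) are
  out of the package's scope; the synthetic smoke runs substitute for them.
* Wall-clock latency is reported for information only
  (`bench_inference`) — the testable claim is that the deployed form is
  never slower than the training form on the same host, and the layer-level
  example shows an order-of-magnitude gain for the RepMLP block itself.
* The generator renders geometric leaf cartoons, not photorealistic foliage.
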