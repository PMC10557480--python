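# mobile-repmlp

A lightweight convolutional/MLP hybrid for crop-leaf disease classification
on edge devices, implemented as a pure NumPy library: the network blocks, an
exact structural re-parameterization for deployment, an analytic
parameter/FLOP profiler, a synthetic leaf-image pipeline, and an SGD training
loop with backpropagation derived by hand for every layer.

## The problem and the model

Field diagnosis of crop diseases increasingly runs on phones and edge boxes,
where model size matters more than raw accuracy.  MobileNetV2 is the usual
starting point; most of its parameters sit in the 1×1 *expansion*
convolutions of its inverted-residual bottlenecks (expand ×t → 3×3 depthwise
→ project).  **MobileNet-RepMLP** inverts that design in the late stages:
instead of expanding channels, a `Bottleneck_RepMLP` block *reduces* them by
a factor r with a 1×1 convolution, extracts features at the narrow width with
a **RepMLP** block, and restores the stage width with a second 1×1
convolution.

A RepMLP block tiles the feature map into h×w partitions and mixes them with
fully connected layers:

* a **global perceptron** (per-partition GAP → FC(C→C/ρ) → ReLU → FC(C/ρ→C),
  added back) that summarises each partition,
* a **partition perceptron** — a grouped FC over the flattened partition
  followed by BN — the main position-aware mixer, and
* a **local perceptron** — parallel 1×1/3×3/5×5 depthwise conv+BN branches
  that inject local priors, *at training time only*: because convolution is
  linear, every conv+BN branch folds exactly into the partition FC for
  deployment (`reparameterize`), leaving a single grouped matmul per
  partition.

ECA channel attention (GAP → adaptive-width 1-D conv → sigmoid gate) follows
every block, and Hardswish replaces ReLU6 inside the modified blocks.  The
depthwise-separable factorisation underlying the backbone costs
`1/N + 1/K²` of a standard K×K convolution with N output channels — about
1/9 for K=3 (`cost_ratio`).

With RepMLP in stages B5–B7 and r=4, the 25-class model holds **0.91 M**
parameters against **2.26 M** for the matched MobileNetV2 — a **59.7 %**
reduction — while the deployment fold changes neither logits (≤1e-4) nor the
reported parameter count.

## Worked example

```python
from mobilerepmlp import ModelSpec, build_model, percent_reduction, profile

default = build_model(ModelSpec())      # B5-B7 RepMLP, r=4, ECA, Hardswish, 25 classes
baseline = build_model(ModelSpec(num_classes=25, repmlp_stages=frozenset(),
                                 use_eca=False, use_hardswish=False))
print(profile(default, (3, 224, 224)).params_m)    # 0.91
print(profile(baseline, (3, 224, 224)).params_m)   # 2.26
print(profile(baseline, (3, 224, 224)).flops_m)    # 319.3
```

`0.91` and `2.26` are trainable-parameter totals in millions; `319.3` is the
baseline's per-image FLOPs (in millions) under the profiler's pinned
convention (one multiply-accumulate = 1 FLOP, BN 2 ops/element, activations
1 op/element).

The `examples/` directory holds one short script per capability — building
and profiling, the re-parameterization fold, the synthetic dataset pipeline,
a desk-scale training run (4 classes, 200 synthetic images, 64×64, 5 epochs,
reaching 100 % test accuracy in about a minute), and the variant size grid.
A thin CLI mirrors the library:

```bash
mobile-repmlp build --summary
mobile-repmlp gen-data --classes 4 --per-class 50 --out runs/demo
mobile-repmlp split --manifest runs/demo/manifest.csv --ratio 4:1 --seed 0
mobile-repmlp train --manifest runs/demo/manifest.csv --out runs/demo --epochs 5 --batch-size 16
```

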