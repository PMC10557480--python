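"""Size grid over the architecture's two study axes.

Axis 1: which bottleneck stages get the RepMLP block (B4-B7 down to none).
Axis 2: the channel-reduction factor r inside each RepMLP block.
The 10-class variants are small-image models (40x40 input, stride-1 stem);
their partition FCs are tiny, which is why their totals sit far below the
224x224 default.
"""

from mobilerepmlp import build_model, count_params, make_variant

print("stage grid (r=4, 10 classes):")
for stages in ({4, 5, 6, 7}, {5, 6, 7}, {6, 7}, {7}, set()):
    model = build_model(make_variant(stages, r=4, num_classes=10))
    label = "B" + "+B".join(map(str, sorted(stages))) if stages else "none (MobileNetV2)"
    print(f"  repmlp stages {label:<22}: {count_params(model)/1e6:.2f} M")

print("reduction-factor grid (stages B5-B7, 10 classes):")
for r in (8, 4, 2):
    model = build_model(make_variant({5, 6, 7}, r=r, num_classes=10))
    print(f"  r={r}: {count_params(model)/1e6:.2f} M")
# More replaced stages and larger r both shrink the model; the accuracy cost
# of each step is what the full training study trades off.
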