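"""Build the improved model and its MobileNetV2 baseline; compare sizes.

The improved network swaps the last three bottleneck stages for
channel-reducing RepMLP blocks (r=4), adds ECA channel attention and uses
Hardswish in the modified blocks.  The profiler counts trainable parameters
and, under one pinned convention, FLOPs and multiply-adds per 224x224 image.
"""

from mobilerepmlp import ModelSpec, build_model, percent_reduction, profile

default = build_model(ModelSpec())  # B5-B7 RepMLP, r=4, ECA, Hardswish, 25 classes
baseline = build_model(ModelSpec(num_classes=25, repmlp_stages=frozenset(),
                                 use_eca=False, use_hardswish=False))

rep_new = profile(default, (3, 224, 224))
rep_v2 = profile(baseline, (3, 224, 224))

print(f"MobileNet-RepMLP : {rep_new.params_m:.2f} M params, "
      f"{rep_new.flops_m:.1f} M FLOPs, {rep_new.madd_m:.1f} M MAdd")
print(f"MobileNetV2      : {rep_v2.params_m:.2f} M params, "
      f"{rep_v2.flops_m:.1f} M FLOPs, {rep_v2.madd_m:.1f} M MAdd")
print(f"parameter reduction: "
      f"{percent_reduction(rep_v2.total_params, rep_new.total_params):.1f} %")
# The parameter reduction comes almost entirely from replacing the widest
# 1x1 expansion convolutions with narrow RepMLP mixers.
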