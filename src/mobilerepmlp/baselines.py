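"""Analytic parameter counts for the comparison baselines.

The comparison tables quote parameter totals for ResNet18 and
ShuffleNetV2 x1.0 heads re-sized to the task's class count.  Only their
parameter budgets matter here, so these are structural enumerations (layer
name, parameter count), not runnable networks.  The enumerations follow the
canonical reference implementations of each architecture; with a 1000-class
head they reproduce the well-known totals (11,689,512 and 2,278,604).
"""

from __future__ import annotations

__all__ = ["resnet18_params", "shufflenet_v2_x1_params"]


def _conv(cin, cout, k, groups=1):
    return k * k * (cin // groups) * cout


def _bn(c):
    return 2 * c


def resnet18_params(num_classes: int = 1000) -> tuple[int, list[tuple[str, int]]]:
    """(total, per-layer rows) for ResNet18 with a ``num_classes`` head."""
    rows: list[tuple[str, int]] = [("conv1", _conv(3, 64, 7)), ("bn1", _bn(64))]
    cin = 64
    for li, cout in enumerate((64, 128, 256, 512), start=1):
        for bi in range(2):
            stride_block = bi == 0 and li > 1
            rows.append((f"layer{li}.{bi}.conv1", _conv(cin if bi == 0 else cout, cout, 3)))
            rows.append((f"layer{li}.{bi}.bn1", _bn(cout)))
            rows.append((f"layer{li}.{bi}.conv2", _conv(cout, cout, 3)))
            rows.append((f"layer{li}.{bi}.bn2", _bn(cout)))
            if stride_block:
                rows.append((f"layer{li}.{bi}.downsample.conv", _conv(cin, cout, 1)))
                rows.append((f"layer{li}.{bi}.downsample.bn", _bn(cout)))
        cin = cout
    rows.append(("fc", 512 * num_classes + num_classes))
    return sum(p for _, p in rows), rows


def shufflenet_v2_x1_params(num_classes: int = 1000) -> tuple[int, list[tuple[str, int]]]:
    """(total, per-layer rows) for ShuffleNetV2 x1.0 with a ``num_classes`` head."""
    rows: list[tuple[str, int]] = [("conv1", _conv(3, 24, 3)), ("bn1", _bn(24))]

    def down_unit(name, cin, cout):
        bf = cout // 2
        rows.extend([
            (f"{name}.branch1.dw", _conv(cin, cin, 3, groups=cin)),
            (f"{name}.branch1.dw_bn", _bn(cin)),
            (f"{name}.branch1.pw", _conv(cin, bf, 1)),
            (f"{name}.branch1.pw_bn", _bn(bf)),
            (f"{name}.branch2.pw1", _conv(cin, bf, 1)),
            (f"{name}.branch2.pw1_bn", _bn(bf)),
            (f"{name}.branch2.dw", _conv(bf, bf, 3, groups=bf)),
            (f"{name}.branch2.dw_bn", _bn(bf)),
            (f"{name}.branch2.pw2", _conv(bf, bf, 1)),
            (f"{name}.branch2.pw2_bn", _bn(bf)),
        ])

    def basic_unit(name, c):
        bf = c // 2
        rows.extend([
            (f"{name}.pw1", _conv(bf, bf, 1)),
            (f"{name}.pw1_bn", _bn(bf)),
            (f"{name}.dw", _conv(bf, bf, 3, groups=bf)),
            (f"{name}.dw_bn", _bn(bf)),
            (f"{name}.pw2", _conv(bf, bf, 1)),
            (f"{name}.pw2_bn", _bn(bf)),
        ])

    cin = 24
    for si, (cout, repeats) in enumerate(((116, 4), (232, 8), (464, 4)), start=2):
        down_unit(f"stage{si}.0", cin, cout)
        for bi in range(1, repeats):
            basic_unit(f"stage{si}.{bi}", cout)
        cin = cout
    rows.append(("conv5", _conv(464, 1024, 1)))
    rows.append(("conv5_bn", _bn(1024)))
    rows.append(("fc", 1024 * num_classes + num_classes))
    return sum(p for _, p in rows), rows
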