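"""MobileNet-RepMLP assembly.

The backbone is MobileNetV2: a stride-2 stem to 32 channels, seven bottleneck
stages with output channels (16, 24, 32, 64, 96, 160, 320), a 1x1 head to
1280 channels, global average pooling and a linear classifier.  Any subset of
stages B4..B7 can be swapped for a ``Bottleneck_RepMLP`` stage that

1. *reduces* channels by a factor ``r`` with a 1x1 conv (+BN+Hardswish) —
   the opposite of the usual t-fold expansion, which is where the parameter
   savings come from,
2. runs a RepMLP block at the reduced width on the incoming resolution,
3. downsamples with a 2x2 stride-2 average pool when the stage strides
   (the partition FC cannot stride), and
4. restores the stage's output channels with a second 1x1 conv (+BN).

A residual connection is added when shape-compatible, and an ECA gate can
follow every block.  Each RepMLP stage is a single block; the partition side
is the largest divisor of the incoming map not exceeding 7 (so 14x14 and 7x7
maps both use 7x7 partitions).

Parameter budget note: the RepMLP partition FC holds ``C/g * (h*w)^2``
weights per group, so the model's size depends on the input resolution.
The 25-class default is defined at 224x224; the 10-class study variants are
defined at 40x40 (zero-padded CIFAR-sized input) with a stride-1 stem, the
usual small-image adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import ECA, ConvBNAct, InvertedResidual
from .nn import GlobalAvgPool, Layer, Linear, AvgPool2d
from .repmlp import RepMLP, RepMLPSpec

__all__ = [
    "StageSpec",
    "ModelSpec",
    "BottleneckRepMLP",
    "MobileNetRepMLP",
    "build_model",
    "make_variant",
    "DEFAULT_STAGES",
]

# Table of backbone stages: (expansion t, out channels c, repeats n, stride s)
DEFAULT_STAGES: tuple[tuple[int, int, int, int], ...] = (
    (1, 16, 1, 1),
    (6, 24, 2, 2),
    (6, 32, 3, 2),
    (6, 64, 4, 2),
    (6, 96, 3, 1),
    (6, 160, 3, 2),
    (6, 320, 1, 1),
)

_VALID_R = (2, 4, 8)


@dataclass(frozen=True)
class StageSpec:
    """One backbone stage: ``standard`` inverted residuals or a ``repmlp``
    reduction stage.  For standard stages ``t`` is the expansion multiple;
    for repmlp stages the width is ``in_channels // r``."""

    kind: str  # "standard" | "repmlp"
    t: int
    out_channels: int
    repeats: int
    stride: int
    r: int = 4

    def __post_init__(self):
        if self.kind not in ("standard", "repmlp"):
            raise ValueError(f"unknown stage kind {self.kind!r}")
        if self.kind == "repmlp" and self.r not in _VALID_R:
            raise ValueError(f"reduction factor r must be one of {_VALID_R}")
        if self.stride not in (1, 2):
            raise ValueError("stage stride must be 1 or 2")


@dataclass(frozen=True)
class ModelSpec:
    """Full model configuration."""

    num_classes: int = 25
    repmlp_stages: frozenset[int] = frozenset({5, 6, 7})
    r: int = 4
    use_eca: bool = True
    use_hardswish: bool = True
    input_size: int = 224
    stem_stride: int = 2
    seed: int = 0

    def __post_init__(self):
        if not set(self.repmlp_stages) <= {4, 5, 6, 7}:
            raise ValueError("repmlp stages must be a subset of {B4..B7}")
        if self.repmlp_stages and self.r not in _VALID_R:
            raise ValueError(f"reduction factor r must be one of {_VALID_R}")

    def stages(self) -> list[StageSpec]:
        out = []
        for idx, (t, c, n, s) in enumerate(DEFAULT_STAGES, start=1):
            if idx in self.repmlp_stages:
                out.append(StageSpec("repmlp", t, c, 1, s, r=self.r))
            else:
                out.append(StageSpec("standard", t, c, n, s))
        return out


def largest_partition(size: int, cap: int = 7) -> int:
    """Largest divisor of ``size`` not exceeding ``cap``."""
    for d in range(min(size, cap), 0, -1):
        if size % d == 0:
            return d
    return 1


class BottleneckRepMLP(Layer):
    """Reduce -> RepMLP -> (pool if striding) -> restore, with optional skip."""

    def __init__(self, in_channels: int, out_channels: int, r: int, stride: int,
                 map_size: int, use_hardswish: bool = True, rng=None):
        if in_channels % r:
            raise ValueError(f"input channels {in_channels} not divisible by r={r}")
        mid = in_channels // r
        act = "hardswish" if use_hardswish else "relu6"
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.use_residual = stride == 1 and in_channels == out_channels
        self.reduce = ConvBNAct(in_channels, mid, 1, act=act, rng=rng)
        h = largest_partition(map_size)
        self.repmlp = RepMLP(RepMLPSpec(mid, map_size, map_size, h, h), rng=rng)
        self.pool = AvgPool2d(2, 2) if stride == 2 else None
        self.restore = ConvBNAct(mid, out_channels, 1, act=None, rng=rng)
        if self.use_residual:
            # start residual blocks as identity: eases optimisation of deep stacks
            self.restore.bn.gamma.data[...] = 0.0

    def forward(self, x, training=False):
        out = self.reduce.forward(x, training)
        out = self.repmlp.forward(out, training)
        if self.pool is not None:
            out = self.pool.forward(out, training)
        out = self.restore.forward(out, training)
        if self.use_residual:
            out = out + x
        return out

    def backward(self, grad):
        g = self.restore.backward(grad)
        if self.pool is not None:
            g = self.pool.backward(g)
        g = self.repmlp.backward(g)
        g = self.reduce.backward(g)
        if self.use_residual:
            g = g + grad
        return g


class MobileNetRepMLP(Layer):
    """The assembled network; ``forward`` maps (N, 3, S, S) to (N, classes)."""

    def __init__(self, spec: ModelSpec):
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.stem = ConvBNAct(3, 32, 3, stride=spec.stem_stride, padding=1,
                              act="relu6", rng=rng)
        fm = self._stem_out(spec.input_size)
        cin = 32
        self.blocks: list[Layer] = []
        self.block_names: list[str] = []
        for idx, stage in enumerate(spec.stages(), start=1):
            for rep in range(stage.repeats):
                stride = stage.stride if rep == 0 else 1
                if stage.kind == "repmlp":
                    blk = BottleneckRepMLP(cin, stage.out_channels, stage.r,
                                           stride, fm,
                                           use_hardswish=spec.use_hardswish,
                                           rng=rng)
                    if stride == 2:
                        fm = (fm - 2) // 2 + 1
                else:
                    if stride == 2:
                        fm = (fm + 2 - 3) // 2 + 1
                    blk = InvertedResidual(cin, stage.out_channels, stage.t,
                                           stride, rng=rng)
                self.blocks.append(blk)
                self.block_names.append(f"b{idx}.{rep}")
                if spec.use_eca:
                    self.blocks.append(ECA(stage.out_channels, rng=rng))
                    self.block_names.append(f"b{idx}.{rep}.eca")
                cin = stage.out_channels
        self.head = ConvBNAct(320, 1280, 1, act="hardswish" if spec.use_hardswish else "relu6",
                              rng=rng)
        self.pool = GlobalAvgPool()
        self.classifier = Linear(1280, spec.num_classes, bias=True, rng=rng)
        self.final_map = fm

    def _stem_out(self, size: int) -> int:
        return (size + 2 - 3) // self.stem.conv.stride + 1

    def forward(self, x, training=False):
        out = self.stem.forward(x, training)
        for blk in self.blocks:
            out = blk.forward(out, training)
        out = self.head.forward(out, training)
        out = self.pool.forward(out, training)
        return self.classifier.forward(out, training)

    def backward(self, grad):
        g = self.classifier.backward(grad)
        g = self.pool.backward(g)
        g = self.head.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        return self.stem.backward(g)

    def shape_trace(self) -> list[tuple[str, int, int]]:
        """(block name, out channels, out map side) for every block."""
        fm = self._stem_out(self.spec.input_size)
        trace = [("stem", 32, fm)]
        for name, blk in zip(self.block_names, self.blocks):
            if isinstance(blk, ECA):
                continue
            if isinstance(blk, BottleneckRepMLP):
                if blk.pool is not None:
                    fm = (fm - 2) // 2 + 1
            elif isinstance(blk, InvertedResidual):
                if blk.stride == 2:
                    fm = (fm + 2 - 3) // 2 + 1
            trace.append((name, blk.out_channels, fm))
        trace.append(("head", 1280, fm))
        return trace

    def sublayers(self):
        yield self.stem
        yield from self.blocks
        yield self.head
        yield self.classifier


def build_model(spec: ModelSpec) -> MobileNetRepMLP:
    """Construct the network described by ``spec``."""
    return MobileNetRepMLP(spec)


def make_variant(stages: set[int] | frozenset[int], r: int = 4,
                 num_classes: int = 10, use_eca: bool = False,
                 use_hardswish: bool = False, seed: int = 0,
                 input_size: int | None = None) -> ModelSpec:
    """Spec for one member of the stage-selection / channel-reduction grids.

    The 10-class study variants are small-image models: they default to a
    40x40 input (CIFAR images zero-padded to 40) with a stride-1 stem.  Any
    other class count defaults to the 224x224 configuration.  An empty stage
    set is the plain MobileNetV2 baseline.
    """
    stages = frozenset(stages)
    if stages and r not in _VALID_R:
        raise ValueError(f"reduction factor r must be one of {_VALID_R}")
    if input_size is None:
        input_size = 40 if num_classes == 10 else 224
    stem_stride = 1 if input_size < 64 else 2
    return ModelSpec(num_classes=num_classes, repmlp_stages=stages, r=r,
                     use_eca=use_eca, use_hardswish=use_hardswish,
                     input_size=input_size, stem_stride=stem_stride, seed=seed)


def reparameterize_model(model: MobileNetRepMLP) -> MobileNetRepMLP:
    """Deploy-form copy of the model: every RepMLP folded, nothing else touched."""
    import copy as _copy
    from .reparam import reparameterize

    out = _copy.deepcopy(model)
    for blk in out.blocks:
        if isinstance(blk, BottleneckRepMLP) and not blk.repmlp.deployed:
            blk.repmlp = reparameterize(blk.repmlp)
    return out
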