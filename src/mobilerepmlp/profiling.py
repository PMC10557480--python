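"""Analytic parameter / FLOP / MAdd profiler under one pinned convention.

Counting convention (applies to every comparison this package makes):

* conv / linear: one multiply-accumulate = **1 FLOP**; a bias adds one op per
  output element.
* batch norm (inference): 2 ops per element (scale + shift).
* activations (ReLU/ReLU6/Hardswish): 1 op per element.
* average pooling: ``k*k`` ops per output element (window sum + scale);
  global pooling analogously ``H*W``.
* residual / branch additions: 1 op per element.
* sigmoid gates: 4 ops per element.
* **MAdd** counts multiplies and adds separately: a conv/linear output
  element with m MACs costs ``2m - 1`` MAdd; elementwise ops count the same
  as FLOPs.

Parameters count every trainable array, including BN scale/shift.  Totals are
reported in millions (M); "Param/M" in the comparison tables means millions
of parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture import BottleneckRepMLP, MobileNetRepMLP
from .blocks import ECA, ConvBNAct, InvertedResidual
from .nn import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GroupedLinear,
    Hardswish,
    Layer,
    Linear,
    ReLU,
    ReLU6,
    Sequential,
)
from .repmlp import RepMLP

__all__ = ["ProfileReport", "count_params", "count_flops", "profile", "percent_reduction"]


@dataclass
class LayerRow:
    name: str
    type: str
    params: int
    flops: int
    madd: int
    out_shape: tuple


@dataclass
class ProfileReport:
    rows: list[LayerRow] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.rows)

    @property
    def total_flops(self) -> int:
        return sum(r.flops for r in self.rows)

    @property
    def total_madd(self) -> int:
        return sum(r.madd for r in self.rows)

    @property
    def params_m(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def flops_m(self) -> float:
        return round(self.total_flops / 1e6, 1)

    @property
    def madd_m(self) -> float:
        return round(self.total_madd / 1e6, 1)

    def to_dict(self) -> dict:
        return {
            "total_params": self.total_params,
            "params_M": self.params_m,
            "flops_M": self.flops_m,
            "madd_M": self.madd_m,
            "layers": [vars(r) for r in self.rows],
        }

    def table(self) -> str:
        lines = [f"{'layer':<28}{'type':<18}{'params':>10}{'flops':>14}{'madd':>14}  out"]
        for r in self.rows:
            lines.append(f"{r.name:<28}{r.type:<18}{r.params:>10}{r.flops:>14}{r.madd:>14}  {r.out_shape}")
        lines.append(f"{'TOTAL':<28}{'':<18}{self.total_params:>10}{self.total_flops:>14}{self.total_madd:>14}")
        lines.append(f"params {self.params_m} M | flops {self.flops_m} M | madd {self.madd_m} M")
        return "\n".join(lines)


class _Profiler:
    def __init__(self):
        self.report = ProfileReport()

    def add(self, name, type_, params, flops, madd, shape):
        self.report.rows.append(LayerRow(name, type_, int(params), int(flops), int(madd), tuple(shape)))

    # -- leaf layers -------------------------------------------------------
    def conv(self, name, layer: Conv2d, c, h, w):
        ho, wo = layer.out_shape(h, w)
        macs_per = layer.kernel_size ** 2 * (layer.in_channels // layer.groups)
        out_elems = layer.out_channels * ho * wo
        flops = out_elems * macs_per
        madd = out_elems * (2 * macs_per - 1)
        params = layer.weight.size
        if layer.bias is not None:
            params += layer.bias.size
            flops += out_elems
            madd += out_elems
        self.add(name, "conv", params, flops, madd, (layer.out_channels, ho, wo))
        return layer.out_channels, ho, wo

    def bn(self, name, layer: BatchNorm2d, c, h, w):
        elems = c * h * w
        self.add(name, "batchnorm", layer.gamma.size + layer.beta.size, 2 * elems, 2 * elems, (c, h, w))
        return c, h, w

    def act(self, name, kind, c, h, w):
        elems = c * h * w
        self.add(name, kind, 0, elems, elems, (c, h, w))
        return c, h, w

    def add_op(self, name, c, h, w):
        elems = c * h * w
        self.add(name, "add", 0, elems, elems, (c, h, w))

    def linear(self, name, layer, c):
        if isinstance(layer, GroupedLinear):
            macs = layer.out_features * (layer.in_features // layer.groups)
            params = layer.weight.size
        else:
            macs = layer.out_features * layer.in_features
            params = layer.weight.size
        flops, madd = macs, 2 * macs - layer.out_features
        if layer.bias is not None:
            params += layer.bias.size
            flops += layer.out_features
            madd += layer.out_features
        self.add(name, "linear", params, flops, madd, (layer.out_features,))
        return layer.out_features

    def pool(self, name, layer: AvgPool2d, c, h, w):
        ho, wo = layer.out_shape(h, w)
        ops = c * ho * wo * layer.kernel_size ** 2
        self.add(name, "avgpool", 0, ops, ops, (c, ho, wo))
        return c, ho, wo

    def gap(self, name, c, h, w):
        ops = c * h * w
        self.add(name, "globalpool", 0, ops, ops, (c,))
        return c

    def eca(self, name, layer: ECA, c, h, w):
        # gap + 1-D conv + sigmoid + per-element scale
        flops = c * h * w + c * layer.kernel_size + 4 * c + c * h * w
        self.add(name, "eca", layer.weight.size, flops, flops, (c, h, w))
        return c, h, w

    # -- composites --------------------------------------------------------
    def conv_bn_act(self, name, layer: ConvBNAct, c, h, w):
        c, h, w = self.conv(f"{name}.conv", layer.conv, c, h, w)
        c, h, w = self.bn(f"{name}.bn", layer.bn, c, h, w)
        if len(layer.layers) > 2:
            kind = type(layer.layers[2]).__name__.lower()
            self.act(f"{name}.act", kind, c, h, w)
        return c, h, w

    def inverted_residual(self, name, layer: InvertedResidual, c, h, w):
        cin, hin, win = c, h, w
        if layer.expand is not None:
            c, h, w = self.conv_bn_act(f"{name}.expand", layer.expand, c, h, w)
        c, h, w = self.conv_bn_act(f"{name}.dw", layer.depthwise, c, h, w)
        c, h, w = self.conv_bn_act(f"{name}.project", layer.project, c, h, w)
        if layer.use_residual:
            self.add_op(f"{name}.residual", c, h, w)
        return c, h, w

    def repmlp(self, name, layer: RepMLP, c, h, w):
        s = layer.spec
        npart = s.num_partitions
        hw = s.part_h * s.part_w
        # global perceptron, per partition
        self.add(f"{name}.global.gap", "globalpool", 0, npart * c * hw, npart * c * hw,
                 (npart, c))
        gp = layer.global_perceptron
        for i, fc in enumerate((gp.fc1, gp.fc2)):
            macs = fc.out_features * fc.in_features
            flops = npart * (macs + fc.out_features)
            madd = npart * (2 * macs - fc.out_features + fc.out_features)
            self.add(f"{name}.global.fc{i + 1}", "linear",
                     fc.weight.size + fc.bias.size, flops, madd, (npart, fc.out_features))
        self.add(f"{name}.global.relu", "relu", 0, npart * gp.fc1.out_features,
                 npart * gp.fc1.out_features, (npart, gp.fc1.out_features))
        self.add_op(f"{name}.global.add", npart * c, s.part_h, s.part_w)
        # partition perceptron
        fc = layer.partition_perceptron.fc
        macs = fc.out_features * (fc.in_features // fc.groups)
        flops, madd = npart * macs, npart * (2 * macs - fc.out_features)
        params = fc.weight.size
        if fc.bias is not None:
            params += fc.bias.size
            flops += npart * fc.out_features
            madd += npart * fc.out_features
        self.add(f"{name}.partition.fc", "grouped_linear", params, flops, madd,
                 (npart, s.out_channels, s.part_h, s.part_w))
        if layer.partition_perceptron.bn is not None:
            elems = npart * s.out_channels * hw
            self.add(f"{name}.partition.bn", "batchnorm",
                     2 * s.out_channels, 2 * elems, 2 * elems,
                     (npart, s.out_channels, s.part_h, s.part_w))
        # local perceptron (training form only)
        if layer.local_perceptron is not None:
            for conv, bn in zip(layer.local_perceptron.convs, layer.local_perceptron.bns):
                k = conv.kernel_size
                macs_per = k * k * (conv.in_channels // conv.groups)
                out_elems = npart * conv.out_channels * hw
                self.add(f"{name}.local.conv{k}x{k}", "conv", conv.weight.size,
                         out_elems * macs_per, out_elems * (2 * macs_per - 1),
                         (npart, conv.out_channels, s.part_h, s.part_w))
                self.add(f"{name}.local.bn{k}x{k}", "batchnorm", 2 * conv.out_channels,
                         2 * out_elems, 2 * out_elems,
                         (npart, conv.out_channels, s.part_h, s.part_w))
                self.add_op(f"{name}.local.add{k}x{k}", npart * conv.out_channels,
                            s.part_h, s.part_w)
        return s.out_channels, s.height, s.width

    def bottleneck_repmlp(self, name, layer: BottleneckRepMLP, c, h, w):
        c, h, w = self.conv_bn_act(f"{name}.reduce", layer.reduce, c, h, w)
        c, h, w = self.repmlp(f"{name}.repmlp", layer.repmlp, c, h, w)
        if layer.pool is not None:
            c, h, w = self.pool(f"{name}.pool", layer.pool, c, h, w)
        c, h, w = self.conv_bn_act(f"{name}.restore", layer.restore, c, h, w)
        if layer.use_residual:
            self.add_op(f"{name}.residual", c, h, w)
        return c, h, w

    def dispatch(self, name, layer, c, h, w):
        if isinstance(layer, ConvBNAct):
            return self.conv_bn_act(name, layer, c, h, w)
        if isinstance(layer, Conv2d):
            return self.conv(name, layer, c, h, w)
        if isinstance(layer, BatchNorm2d):
            return self.bn(name, layer, c, h, w)
        if isinstance(layer, (ReLU, ReLU6, Hardswish)):
            return self.act(name, type(layer).__name__.lower(), c, h, w)
        if isinstance(layer, InvertedResidual):
            return self.inverted_residual(name, layer, c, h, w)
        if isinstance(layer, BottleneckRepMLP):
            return self.bottleneck_repmlp(name, layer, c, h, w)
        if isinstance(layer, RepMLP):
            return self.repmlp(name, layer, c, h, w)
        if isinstance(layer, ECA):
            return self.eca(name, layer, c, h, w)
        if isinstance(layer, AvgPool2d):
            return self.pool(name, layer, c, h, w)
        if isinstance(layer, Sequential):
            for i, sub in enumerate(layer):
                c_h_w = self.dispatch(f"{name}.{i}", sub, c, h, w)
                c, h, w = c_h_w
            return c, h, w
        raise TypeError(f"cannot profile layer of type {type(layer).__name__}")


def profile(network, input_shape: tuple[int, int, int] = (3, 224, 224)) -> ProfileReport:
    """Per-layer parameter and operation counts for a built network.

    ``input_shape`` is ``(channels, height, width)`` for a single image; the
    counts are per image.  Works for :class:`MobileNetRepMLP` and for plain
    :class:`Sequential` stacks of the supported layer types.
    """
    c, h, w = input_shape
    p = _Profiler()
    if isinstance(network, MobileNetRepMLP):
        if h != network.spec.input_size:
            raise ValueError(
                f"model was built for {network.spec.input_size}x{network.spec.input_size} input")
        c, h, w = p.conv_bn_act("stem", network.stem, c, h, w)
        for name, blk in zip(network.block_names, network.blocks):
            c, h, w = p.dispatch(name, blk, c, h, w)
        c, h, w = p.conv_bn_act("head", network.head, c, h, w)
        c = p.gap("avgpool", c, h, w)
        p.linear("classifier", network.classifier, c)
    elif isinstance(network, Linear):
        p.linear("linear", network, c)
    else:
        result = p.dispatch("net", network, c, h, w)
    return p.report


def count_params(network) -> int:
    """Total trainable parameters (weights, biases, BN scale/shift)."""
    if isinstance(network, Layer):
        return network.num_params()
    raise TypeError("count_params expects a Layer")


def count_flops(network, input_shape: tuple[int, int, int] = (3, 224, 224)) -> tuple[int, int]:
    """(FLOPs, MAdd) per image under the pinned convention."""
    rep = profile(network, input_shape)
    return rep.total_flops, rep.total_madd


def percent_reduction(reference: float, candidate: float) -> float:
    """Percent decrease of ``candidate`` relative to ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - candidate) / reference
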