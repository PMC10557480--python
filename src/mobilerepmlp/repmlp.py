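"""RepMLP: an MLP-style block with a training-time convolutional side path.

The block tiles the feature map into non-overlapping ``h x w`` partitions and
runs three branches:

* **global perceptron** — each partition is average-pooled to a channel
  vector, squeezed through two fully connected layers (reduction ``rho``,
  ReLU in between) and added back, giving every partition a cheap summary of
  itself;
* **partition perceptron** — a grouped fully connected layer over the
  flattened partition (``C*h*w`` features, channel-major), followed by batch
  normalisation; this is the block's main, position-aware mixer;
* **local perceptron** — a set of small padded convolutions (kernel sizes
  1/3/5 by default), each followed by BN, summed into the partition
  perceptron output.  It exists only at training time: because convolution
  is linear, every conv+BN branch can be folded exactly into the partition
  FC weight matrix for deployment (see :mod:`mobilerepmlp.reparam`).

Partition order is row-major over the ``(H/h, W/w)`` grid; this ordering is
part of the serialized-weight contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    GroupedLinear,
    Layer,
    Linear,
    ReLU,
)

__all__ = [
    "RepMLPSpec",
    "partition_split",
    "partition_merge",
    "GlobalPerceptron",
    "PartitionPerceptron",
    "LocalPerceptron",
    "RepMLP",
]


@dataclass(frozen=True)
class RepMLPSpec:
    """Hyper-parameters of one RepMLP block.

    ``in_channels`` C feeds a block producing ``out_channels`` o on an
    ``H x W`` map tiled into ``h x w`` partitions; the partition FC and the
    local convolutions share the group count ``g`` (required for exact
    re-parameterization); the global perceptron shrinks channels by
    ``global_reduction``.
    """

    in_channels: int
    height: int
    width: int
    part_h: int
    part_w: int
    groups: int = 0  # 0 -> per-channel (groups == in_channels)
    out_channels: int = 0  # 0 -> same as in_channels
    global_reduction: int = 4
    local_kernels: tuple[int, ...] = (1, 3, 5)
    bn_epsilon: float = 1e-5

    def __post_init__(self):
        object.__setattr__(self, "groups", self.groups or self.in_channels)
        object.__setattr__(self, "out_channels", self.out_channels or self.in_channels)
        if self.height % self.part_h or self.width % self.part_w:
            raise ValueError("map size must be divisible by the partition size")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError("channels must be divisible by groups")
        if not set(self.local_kernels) <= {1, 3, 5}:
            raise ValueError("local kernels must be a subset of {1, 3, 5}")
        for k in self.local_kernels:
            if k % 2 == 0:
                raise ValueError("local kernels must be odd")

    @property
    def num_partitions(self) -> int:
        return (self.height // self.part_h) * (self.width // self.part_w)


def partition_split(x: np.ndarray, h: int, w: int) -> np.ndarray:
    """Tile ``(N, C, H, W)`` into ``(N * (H/h) * (W/w), C, h, w)``.

    Partitions are ordered row-major over the partition grid; the exact
    inverse is :func:`partition_merge`.
    """
    n, c, H, W = x.shape
    if H % h or W % w:
        raise ValueError(f"map {H}x{W} not divisible by partition {h}x{w}")
    nh, nw = H // h, W // w
    parts = x.reshape(n, c, nh, h, nw, w)
    parts = parts.transpose(0, 2, 4, 1, 3, 5)  # (n, nh, nw, c, h, w)
    return np.ascontiguousarray(parts).reshape(n * nh * nw, c, h, w)


def partition_merge(parts: np.ndarray, n: int, H: int, W: int) -> np.ndarray:
    """Exact inverse of :func:`partition_split`."""
    p, c, h, w = parts.shape
    nh, nw = H // h, W // w
    if p != n * nh * nw:
        raise ValueError("partition count inconsistent with target shape")
    x = parts.reshape(n, nh, nw, c, h, w).transpose(0, 3, 1, 4, 2, 5)
    return np.ascontiguousarray(x).reshape(n, c, H, W)


class GlobalPerceptron(Layer):
    """Per-partition squeeze-and-add: GAP -> FC(C -> C/rho) -> ReLU ->
    FC(C/rho -> C), broadcast back over the partition and added to it."""

    def __init__(self, channels: int, reduction: int, rng=None):
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.fc1 = Linear(channels, hidden, bias=True, rng=rng)
        self.act = ReLU()
        self.fc2 = Linear(hidden, channels, bias=True, rng=rng)
        self._cache = None

    def forward(self, parts: np.ndarray, training: bool = False) -> np.ndarray:
        if parts.shape[1] != self.channels:
            raise ValueError("channel mismatch in global perceptron")
        gap = parts.mean(axis=(2, 3))
        v = self.fc2.forward(self.act.forward(self.fc1.forward(gap, training), training), training)
        if training:
            self._cache = parts.shape
        return parts + v[:, :, None, None]

    def backward(self, grad):
        _, _, h, w = self._cache
        dv = grad.sum(axis=(2, 3))
        dgap = self.fc1.backward(self.act.backward(self.fc2.backward(dv)))
        return grad + dgap[:, :, None, None] / (h * w)


class PartitionPerceptron(Layer):
    """Grouped FC over the flattened partition, then BN over output channels.

    In deployed form the BN is folded away and the FC carries a bias.
    """

    def __init__(self, spec: RepMLPSpec, rng=None, deployed: bool = False):
        self.spec = spec
        hw = spec.part_h * spec.part_w
        self.fc = GroupedLinear(spec.in_channels * hw, spec.out_channels * hw,
                                spec.groups, bias=deployed, rng=rng)
        self.bn = None if deployed else BatchNorm2d(spec.out_channels, eps=spec.bn_epsilon)
        self.deployed = deployed

    def forward(self, parts, training=False):
        s = self.spec
        p = parts.shape[0]
        flat = parts.reshape(p, s.in_channels * s.part_h * s.part_w)
        out = self.fc.forward(flat, training)
        out = out.reshape(p, s.out_channels, s.part_h, s.part_w)
        if self.bn is not None:
            out = self.bn.forward(out, training)
        return out

    def backward(self, grad):
        s = self.spec
        if self.bn is not None:
            grad = self.bn.backward(grad)
        p = grad.shape[0]
        flat = grad.reshape(p, s.out_channels * s.part_h * s.part_w)
        dx = self.fc.backward(flat)
        return dx.reshape(p, s.in_channels, s.part_h, s.part_w)


class LocalPerceptron(Layer):
    """Sum of padded conv+BN branches over the partitions (training only)."""

    def __init__(self, spec: RepMLPSpec, rng=None):
        self.spec = spec
        self.convs = []
        self.bns = []
        for k in spec.local_kernels:
            self.convs.append(Conv2d(spec.in_channels, spec.out_channels, k,
                                     padding=k // 2, groups=spec.groups,
                                     bias=False, rng=rng))
            self.bns.append(BatchNorm2d(spec.out_channels, eps=spec.bn_epsilon))

    def forward(self, parts, training=False):
        out = None
        for conv, bn in zip(self.convs, self.bns):
            y = bn.forward(conv.forward(parts, training), training)
            out = y if out is None else out + y
        if out is None:
            out = np.zeros((parts.shape[0], self.spec.out_channels,
                            self.spec.part_h, self.spec.part_w), dtype=parts.dtype)
        return out

    def backward(self, grad):
        dx = None
        for conv, bn in zip(self.convs, self.bns):
            g = conv.backward(bn.backward(grad))
            dx = g if dx is None else dx + g
        return dx if dx is not None else np.zeros_like(grad)


class RepMLP(Layer):
    """The full block: split -> global add -> partition FC (+ local convs at
    training time) -> merge.  ``deployed`` blocks have the convolutional side
    path folded into the FC and carry no BN."""

    def __init__(self, spec: RepMLPSpec, rng=None, deployed: bool = False):
        self.spec = spec
        self.deployed = deployed
        self.global_perceptron = GlobalPerceptron(spec.in_channels, spec.global_reduction, rng=rng)
        self.partition_perceptron = PartitionPerceptron(spec, rng=rng, deployed=deployed)
        self.local_perceptron = None if deployed else LocalPerceptron(spec, rng=rng)
        self._cache = None

    def forward(self, x, training=False):
        s = self.spec
        n, c, H, W = x.shape
        if c != s.in_channels or H != s.height or W != s.width:
            raise ValueError(
                f"input {x.shape[1:]} does not match spec "
                f"({s.in_channels}, {s.height}, {s.width})")
        parts = partition_split(x, s.part_h, s.part_w)
        parts = self.global_perceptron.forward(parts, training)
        out = self.partition_perceptron.forward(parts, training)
        if self.local_perceptron is not None:
            out = out + self.local_perceptron.forward(parts, training)
        if training:
            self._cache = n
        return partition_merge(out, n, H, W)

    def backward(self, grad):
        s = self.spec
        n = self._cache
        gparts = partition_split(grad, s.part_h, s.part_w)
        dparts = self.partition_perceptron.backward(gparts)
        if self.local_perceptron is not None:
            dparts = dparts + self.local_perceptron.backward(gparts)
        dparts = self.global_perceptron.backward(dparts)
        return partition_merge(dparts, n, s.height, s.width)
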