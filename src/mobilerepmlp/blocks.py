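"""MobileNetV2 building blocks and efficient channel attention (ECA).

The depthwise-separable factorisation splits a standard K x K convolution
into a per-channel spatial convolution followed by a 1 x 1 channel-mixing
convolution.  For output-channel count N its multiply-accumulate cost is a
fraction ``1/N + 1/K**2`` of the standard convolution — about 1/9 for a
3 x 3 kernel once N is large.

The inverted residual expands channels by a factor ``t``, filters them with a
3 x 3 depthwise convolution, then linearly projects back down; there is no
activation after the final projection, and a skip connection is added when
the block keeps resolution and channel count.

ECA reweights channels with a sigmoid gate computed by a 1-D convolution
across the globally averaged channel vector; the kernel size adapts to the
channel count so wider layers interact across more channels.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Hardswish,
    Layer,
    Param,
    ReLU6,
    Sequential,
    sigmoid,
)

__all__ = [
    "cost_ratio",
    "depthwise_separable_forward",
    "DepthwiseSeparable",
    "InvertedResidual",
    "eca_kernel_size",
    "ECA",
    "ConvBNAct",
]


def cost_ratio(K: int, N: int) -> float:
    """Multiply-accumulate cost of a depthwise-separable convolution relative
    to the standard K x K convolution with N output channels: ``1/N + 1/K**2``.
    """
    if K < 1 or N < 1:
        raise ValueError("kernel size and output channels must be positive")
    return 1.0 / N + 1.0 / (K * K)


class ConvBNAct(Sequential):
    """Conv -> BN -> optional activation, the ubiquitous fused triplet."""

    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1,
                 act: str | None = "relu6", rng=None):
        layers: list[Layer] = [
            Conv2d(cin, cout, k, stride=stride, padding=padding, groups=groups,
                   bias=False, rng=rng),
            BatchNorm2d(cout),
        ]
        if act == "relu6":
            layers.append(ReLU6())
        elif act == "hardswish":
            layers.append(Hardswish())
        elif act is not None:
            raise ValueError(f"unknown activation {act!r}")
        super().__init__(*layers)

    @property
    def conv(self) -> Conv2d:
        return self.layers[0]

    @property
    def bn(self) -> BatchNorm2d:
        return self.layers[1]


class DepthwiseSeparable(Layer):
    """Depthwise K x K convolution followed by a pointwise 1 x 1 convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int | None = None, rng=None):
        if padding is None:
            padding = kernel_size // 2
        self.depthwise = Conv2d(in_channels, in_channels, kernel_size,
                                stride=stride, padding=padding,
                                groups=in_channels, bias=False, rng=rng)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)

    def forward(self, x, training=False):
        return self.pointwise.forward(self.depthwise.forward(x, training), training)

    def backward(self, grad):
        return self.depthwise.backward(self.pointwise.backward(grad))


def depthwise_separable_forward(x: np.ndarray, dw: Conv2d, pw: Conv2d) -> np.ndarray:
    """Apply a depthwise conv then a pointwise 1 x 1 conv.

    Raises ``ValueError`` when the channel bookkeeping between ``x``, ``dw``
    and ``pw`` is inconsistent.
    """
    if dw.groups != dw.in_channels:
        raise ValueError("dw must be depthwise (groups == in_channels)")
    if pw.kernel_size != 1:
        raise ValueError("pw must be a 1x1 convolution")
    if x.shape[1] != dw.in_channels or dw.out_channels != pw.in_channels:
        raise ValueError("channel mismatch between input, dw and pw")
    return pw.forward(dw.forward(x))


class InvertedResidual(Layer):
    """MobileNetV2 block: 1x1 expand (+BN+ReLU6) -> 3x3 depthwise (+BN+ReLU6)
    -> 1x1 project (+BN, linear).  Residual add iff stride 1 and the channel
    count is preserved."""

    def __init__(self, in_channels: int, out_channels: int, expand_t: int,
                 stride: int = 1, rng=None):
        if expand_t < 1:
            raise ValueError("expansion factor must be >= 1")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.use_residual = stride == 1 and in_channels == out_channels
        hidden = in_channels * expand_t
        self.expand = (ConvBNAct(in_channels, hidden, 1, act="relu6", rng=rng)
                       if expand_t != 1 else None)
        self.depthwise = ConvBNAct(hidden, hidden, 3, stride=stride, padding=1,
                                   groups=hidden, act="relu6", rng=rng)
        self.project = ConvBNAct(hidden, out_channels, 1, act=None, rng=rng)
        if self.use_residual:
            # start residual blocks as identity: eases optimisation of deep stacks
            self.project.bn.gamma.data[...] = 0.0

    def forward(self, x, training=False):
        out = x
        if self.expand is not None:
            out = self.expand.forward(out, training)
        out = self.depthwise.forward(out, training)
        out = self.project.forward(out, training)
        if self.use_residual:
            out = out + x
        return out

    def backward(self, grad):
        g = self.project.backward(grad)
        g = self.depthwise.backward(g)
        if self.expand is not None:
            g = self.expand.backward(g)
        if self.use_residual:
            g = g + grad
        return g


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Channel-adaptive 1-D kernel size for ECA.

    ``k = |log2(C)/gamma + b/gamma|`` truncated, then bumped to the nearest
    odd integer >= that value.  Non-decreasing in the channel count.
    """
    if channels < 1:
        raise ValueError("channels must be positive")
    t = int(abs(math.log2(channels) / gamma + b / gamma))
    k = t if t % 2 else t + 1
    return max(k, 1)


class ECA(Layer):
    """Efficient channel attention.

    Global average pooling compresses each channel to a scalar; a shared 1-D
    convolution of adaptive kernel size mixes neighbouring channels; a sigmoid
    turns the result into per-channel gates in (0, 1) that rescale the input.
    Adds only ``k`` parameters.
    """

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0,
                 kernel_size: int | None = None, rng=None):
        k = kernel_size if kernel_size is not None else eca_kernel_size(channels, gamma, b)
        if k % 2 == 0 or k < 1:
            raise ValueError("ECA kernel size must be odd and positive")
        if k > channels:
            raise ValueError("ECA kernel longer than the channel vector")
        self.channels = channels
        self.kernel_size = k
        rng = rng or np.random.default_rng(0)
        self.weight = Param("weight", (rng.uniform(-1, 1, size=k) / math.sqrt(k)).astype(np.float32))
        self._cache = None

    def _conv1d(self, v: np.ndarray) -> np.ndarray:
        """Cross-correlate each row of (N, C) with the shared kernel, zero padded."""
        k = self.kernel_size
        p = k // 2
        vp = np.pad(v, ((0, 0), (p, p)))
        out = np.zeros_like(v)
        for j in range(k):
            out += self.weight.data[j] * vp[:, j : j + v.shape[1]]
        return out

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError("channel mismatch in ECA")
        gap = x.mean(axis=(2, 3))
        z = self._conv1d(gap)
        s = sigmoid(z)
        out = x * s[:, :, None, None]
        if training:
            self._cache = (x, gap, s)
        return out

    def backward(self, grad):
        x, gap, s = self._cache
        n, c, h, w = x.shape
        k = self.kernel_size
        p = k // 2
        dx = grad * s[:, :, None, None]
        ds = (grad * x).sum(axis=(2, 3))
        dz = ds * s * (1.0 - s)
        # weight grad: dz_c contributions from gap_{c+j-p}
        gp = np.pad(gap, ((0, 0), (p, p)))
        for j in range(k):
            self.weight.grad[j] += float((dz * gp[:, j : j + c]).sum())
        # gap grad is the correlation transpose: dgap_i = sum_j w_j dz_{i-j+p}
        dzp = np.pad(dz, ((0, 0), (p, p)))
        dgap = np.zeros_like(gap)
        for j in range(k):
            dgap += self.weight.data[j] * dzp[:, 2 * p - j : 2 * p - j + c]
        dx += dgap[:, :, None, None] / (h * w)
        return dx
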