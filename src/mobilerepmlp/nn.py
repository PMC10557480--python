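"""Minimal array-backed neural-network layers with hand-derived backward passes.

All feature maps are ``float32`` arrays laid out ``(batch, channels, height,
width)``.  Every layer implements

* ``forward(x, training=False)`` — caches whatever backward needs,
* ``backward(grad)`` — accumulates parameter gradients and returns the
  gradient with respect to the layer input,
* ``parameters()`` — flat list of :class:`Param`.

Convolution is im2col + BLAS matmul with full support for stride, padding and
groups (depthwise convolution is the ``groups == in_channels`` case).  Batch
normalisation follows the usual two-mode contract: batch statistics while
training (with running-average updates), frozen running statistics at
inference, which is what makes conv+BN folding exact.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "GroupedLinear",
    "ReLU",
    "ReLU6",
    "Hardswish",
    "AvgPool2d",
    "GlobalAvgPool",
    "Flatten",
    "relu6",
    "hardswish",
    "sigmoid",
    "softmax_cross_entropy",
    "kaiming_uniform",
]


# ---------------------------------------------------------------------------
# parameters and layer protocol
# ---------------------------------------------------------------------------

class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name}, shape={self.data.shape})"


class Layer:
    """Base class; sublayers are discovered from instance attributes."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sublayers(self) -> Iterable["Layer"]:
        for value in vars(self).values():
            if isinstance(value, Layer):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        yield item

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for value in vars(self).values():
            if isinstance(value, Param):
                params.append(value)
        for sub in self.sublayers():
            params.extend(sub.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Param]]:
        out: list[tuple[str, Param]] = []
        for name, value in vars(self).items():
            if isinstance(value, Param):
                out.append((f"{prefix}{name}", value))
        for name, value in vars(self).items():
            if isinstance(value, Layer):
                out.extend(value.named_parameters(f"{prefix}{name}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Layer):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, idx):
        return self.layers[idx]


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def kaiming_uniform(rng: np.random.Generator, shape: Sequence[int], fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, padding: int):
    """Return strided view of patches, shape (N, C, K, K, Ho, Wo)."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    sn, sc, sh, sw = x.strides
    view = as_strided(
        x,
        shape=(n, c, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    return x, view, ho, wo


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with groups; optional bias.

    Weight layout ``(out_channels, in_channels // groups, K, K)``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        if kernel_size < 1 or stride < 1 or padding < 0:
            raise ValueError("invalid convolution geometry")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Param(
            "weight",
            kaiming_uniform(rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in),
        )
        self.bias = Param("bias", np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        n = x.shape[0]
        g = self.groups
        k = self.kernel_size
        cig = self.in_channels // g
        cog = self.out_channels // g
        _, view, ho, wo = _im2col(x, k, self.stride, self.padding)
        cols = np.ascontiguousarray(view).reshape(n, g, cig * k * k, ho * wo)
        w_mat = self.weight.data.reshape(g, cog, cig * k * k)
        out = np.matmul(w_mat[None], cols)  # (N, g, cog, ho*wo)
        out = out.reshape(n, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        if training:
            self._cache = (x.shape, cols, ho, wo)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols, ho, wo = self._cache
        n, _, h, w = x_shape
        g, k, s, p = self.groups, self.kernel_size, self.stride, self.padding
        cig = self.in_channels // g
        cog = self.out_channels // g
        gmat = grad.reshape(n, g, cog, ho * wo)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3))
        # dW: sum over batch of grad @ cols^T
        dw = np.einsum("ngop,ngcp->goc", gmat, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        # dX: scatter W^T @ grad back into padded input
        wt = self.weight.data.reshape(g, cog, cig * k * k)
        dcols = np.matmul(wt.transpose(0, 2, 1)[None], gmat)  # (N, g, cig*k*k, ho*wo)
        dcols = dcols.reshape(n, self.in_channels, k, k, ho, wo)
        dx_pad = np.zeros((n, self.in_channels, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for ki in range(k):
            for kj in range(k):
                dx_pad[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, :, ki, kj]
        if p:
            return dx_pad[:, :, p:-p, p:-p]
        return dx_pad


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param("gamma", np.ones(channels, dtype=np.float32))
        self.beta = Param("beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            count = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * count / max(count - 1, 1)
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mean = self.running_mean
            var = self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if training:
            self._cache = (xhat, inv)
        return out.astype(np.float32, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        # standard batch-norm backward (batch statistics)
        dxhat = grad * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = inv[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        return dx.astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# linear layers
# ---------------------------------------------------------------------------

class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param("weight", kaiming_uniform(rng, (out_features, in_features), in_features))
        self.bias = Param("bias", np.zeros(out_features, dtype=np.float32)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        if training:
            self._cache = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += grad.T @ x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class GroupedLinear(Layer):
    """Block-diagonal linear map: ``groups`` independent (out_pg x in_pg) blocks.

    Input ``(batch, groups * in_pg)`` ordered group-major, i.e. feature
    ``i`` belongs to group ``i // in_pg``.
    """

    def __init__(self, in_features: int, out_features: int, groups: int,
                 bias: bool = False, rng: np.random.Generator | None = None):
        if in_features % groups or out_features % groups:
            raise ValueError("features must be divisible by groups")
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.groups = groups
        in_pg = in_features // groups
        out_pg = out_features // groups
        self.weight = Param("weight", kaiming_uniform(rng, (groups, out_pg, in_pg), in_pg))
        self.bias = Param("bias", np.zeros(out_features, dtype=np.float32)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b = x.shape[0]
        g = self.groups
        xg = x.reshape(b, g, self.in_features // g)
        out = np.einsum("bgi,goi->bgo", xg, self.weight.data, optimize=True)
        out = out.reshape(b, self.out_features)
        if self.bias is not None:
            out += self.bias.data
        if training:
            self._cache = xg
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xg = self._cache
        b = grad.shape[0]
        g = self.groups
        gg = grad.reshape(b, g, self.out_features // g)
        self.weight.grad += np.einsum("bgo,bgi->goi", gg, xg, optimize=True)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        dx = np.einsum("bgo,goi->bgi", gg, self.weight.data, optimize=True)
        return dx.reshape(b, self.in_features)

    def dense_weight(self) -> np.ndarray:
        """The equivalent dense (out x in) block-diagonal matrix."""
        g = self.groups
        out_pg = self.out_features // g
        in_pg = self.in_features // g
        dense = np.zeros((self.out_features, self.in_features), dtype=self.weight.data.dtype)
        for i in range(g):
            dense[i * out_pg : (i + 1) * out_pg, i * in_pg : (i + 1) * in_pg] = self.weight.data[i]
        return dense


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu6(x: np.ndarray) -> np.ndarray:
    """min(max(x, 0), 6), elementwise."""
    return np.clip(x, 0.0, 6.0)


def hardswish(x: np.ndarray) -> np.ndarray:
    """x * relu6(x + 3) / 6 — the smooth, non-monotonic MobileNetV3 activation."""
    return x * np.clip(x + 3.0, 0.0, 6.0) / 6.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    np.negative(np.abs(x), out=out)
    np.exp(out, out=out)
    out = np.where(x >= 0, 1.0 / (1.0 + out), out / (1.0 + out))
    return out.astype(x.dtype, copy=False)


class ReLU(Layer):
    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class ReLU6(Layer):
    def forward(self, x, training=False):
        if training:
            self._mask = (x > 0) & (x < 6)
        return relu6(x)

    def backward(self, grad):
        return grad * self._mask


class Hardswish(Layer):
    def forward(self, x, training=False):
        if training:
            self._x = x
        return hardswish(x)

    def backward(self, grad):
        x = self._x
        d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, x / 3.0 + 0.5))
        return grad * d.astype(grad.dtype)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

class AvgPool2d(Layer):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, training=False):
        k, s, p = self.kernel_size, self.stride, self.padding
        _, view, ho, wo = _im2col(x, k, s, p)
        out = view.mean(axis=(2, 3))
        if training:
            self._cache = (x.shape, ho, wo)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        x_shape, ho, wo = self._cache
        n, c, h, w = x_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        dx_pad = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        gk = grad / (k * k)
        for ki in range(k):
            for kj in range(k):
                dx_pad[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += gk
        if p:
            return dx_pad[:, :, p:-p, p:-p]
        return dx_pad


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w), (n, c, h, w)).astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch. Returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return float(loss), dlogits.astype(np.float32)
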