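"""SGD training loop with cosine-annealed learning rate.

The reference schedule: SGD with momentum, cross-entropy loss, learning rate
annealed from ``lr_max`` to ``lr_min`` over the run by

    lr(t) = lr_min + (lr_max - lr_min) * (1 + cos(pi * t / T)) / 2

applied once per epoch (``T`` = total epochs), so ``lr(0) == lr_max`` and
``lr(T) == lr_min``.  The published configuration uses lr 0.1 -> 0.0001,
batch size 64, 30 epochs; smoke-scale runs shrink the batch so a small
dataset still yields enough update steps.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from .nn import Layer, softmax_cross_entropy

__all__ = ["TrainConfig", "cosine_lr", "SGD", "train", "iterate_minibatches",
           "channel_stats", "standardize", "SMOKE_CONFIG"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 30
    lr_max: float = 0.1
    lr_min: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 4e-5
    seed: int = 0
    input_size: int = 224

    def __post_init__(self):
        if not (self.lr_max > self.lr_min > 0):
            raise ValueError("need lr_max > lr_min > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")


def channel_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and std of a (N, C, H, W) stack, for standardization."""
    mu = X.mean(axis=(0, 2, 3), keepdims=True)
    sd = X.std(axis=(0, 2, 3), keepdims=True)
    return mu, np.maximum(sd, 1e-6)


def standardize(X: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Apply train-set channel statistics; always use the *train* stats on test data."""
    mu, sd = stats
    return ((X - mu) / sd).astype(np.float32)


def smoke_config(seed: int = 0) -> TrainConfig:
    """Desk-scale training configuration for small synthetic datasets.

    Small batches give a 200-image set enough update steps inside 5 epochs;
    the lower peak learning rate keeps momentum SGD stable at that batch size.
    """
    return TrainConfig(batch_size=16, epochs=5, lr_max=0.02, lr_min=1e-4,
                       seed=seed, input_size=64)


SMOKE_CONFIG = smoke_config()


def cosine_lr(t: float, total: float, lr_max: float, lr_min: float) -> float:
    """Cosine-annealed learning rate at step ``t`` of ``total``."""
    if total <= 0:
        raise ValueError("total steps must be positive")
    if not 0 <= t <= total:
        raise ValueError("t must lie in [0, total]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / total))


class SGD:
    """Momentum SGD with decoupled L2 weight decay on the gradients."""

    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def iterate_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _accuracy(model: Layer, X: np.ndarray, y: np.ndarray, batch: int = 64) -> float:
    correct = 0
    for i in range(0, len(X), batch):
        logits = model.forward(X[i : i + batch], training=False)
        correct += int((logits.argmax(axis=1) == y[i : i + batch]).sum())
    return correct / len(X)


def train(model: Layer, X: np.ndarray, y: np.ndarray, config: TrainConfig,
          X_test: np.ndarray | None = None, y_test: np.ndarray | None = None,
          verbose: bool = False):
    """Train ``model`` in place; returns the per-epoch history.

    History rows carry (epoch, lr, mean loss, train accuracy and — when a
    test split is supplied — test accuracy).  Deterministic given
    ``config.seed`` and fixed BLAS threading.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), momentum=config.momentum,
              weight_decay=config.weight_decay)
    history = []
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_max, config.lr_min)
        losses = []
        t0 = time.time()
        for idx in iterate_minibatches(len(X), config.batch_size, rng):
            logits = model.forward(X[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step(lr)
            losses.append(loss)
        row = {
            "epoch": epoch,
            "lr": lr,
            "loss": float(np.mean(losses)),
            "train_acc": _accuracy(model, X, y),
            "seconds": time.time() - t0,
        }
        if X_test is not None:
            row["test_acc"] = _accuracy(model, X_test, y_test)
        history.append(row)
        if verbose:
            print(" ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                           for k, v in row.items()))
    return history
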