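"""Classification metrics and the informational inference-latency benchmark.

Accuracy is trace(confusion)/total; recall and precision are macro-averaged
(per-class values weighted equally), reported in percent.  Classes absent
from the evaluation split are excluded from the macro averages with a
warning — their recall is undefined.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Layer

__all__ = ["MetricsReport", "evaluate", "confusion_metrics", "bench_inference"]


@dataclass
class MetricsReport:
    accuracy: float
    macro_recall: float
    macro_precision: float
    confusion: np.ndarray
    per_class_recall: np.ndarray = field(default=None)
    per_class_precision: np.ndarray = field(default=None)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_recall": self.macro_recall,
            "macro_precision": self.macro_precision,
            "confusion": self.confusion.tolist(),
        }


def confusion_metrics(confusion: np.ndarray) -> MetricsReport:
    """Metrics (in percent) from a (true x predicted) confusion matrix."""
    confusion = np.asarray(confusion, dtype=np.int64)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * np.trace(confusion) / total
    row = confusion.sum(axis=1).astype(np.float64)  # per-class support
    col = confusion.sum(axis=0).astype(np.float64)  # per-class predictions
    diag = np.diag(confusion).astype(np.float64)
    present = row > 0
    if not present.all():
        warnings.warn("classes absent from the evaluation split are excluded "
                      "from macro averages")
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(row > 0, diag / row, np.nan)
        precision = np.where(col > 0, diag / col, np.nan)
    macro_recall = 100.0 * np.nanmean(recall[present])
    # precision for a present class with no predictions counts as 0
    prec_present = np.where(np.isnan(precision), 0.0, precision)[present]
    macro_precision = 100.0 * prec_present.mean()
    return MetricsReport(acc, float(macro_recall), float(macro_precision),
                         confusion, recall * 100.0, precision * 100.0)


def evaluate(model: Layer, X: np.ndarray, y: np.ndarray,
             num_classes: int | None = None, batch: int = 64) -> MetricsReport:
    """Run the model on an evaluation split and compute the report."""
    if len(X) == 0:
        raise ValueError("empty evaluation split")
    k = num_classes or int(y.max()) + 1
    confusion = np.zeros((k, k), dtype=np.int64)
    for i in range(0, len(X), batch):
        logits = model.forward(X[i : i + batch], training=False)
        pred = logits.argmax(axis=1)
        np.add.at(confusion, (y[i : i + batch], pred), 1)
    return confusion_metrics(confusion)


def bench_inference(model: Layer, input_shape=(3, 224, 224), n_images: int = 8,
                    repeats: int = 3, seed: int = 0) -> dict:
    """Mean per-image forward latency in milliseconds (informational only).

    Wall-clock numbers are hardware-bound; the stable, testable claim is the
    *direction*: a re-parameterized model is never slower than its training
    form on the same host.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_images, *input_shape)).astype(np.float32)
    model.forward(x[:1], training=False)  # warm-up
    times = []
    for _ in range(repeats):
        t0 = time.perf_counter()
        model.forward(x, training=False)
        times.append((time.perf_counter() - t0) / n_images * 1000.0)
    return {"ms_per_image": float(np.mean(times)), "repeats": repeats,
            "n_images": n_images}
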