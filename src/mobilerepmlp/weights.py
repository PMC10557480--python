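"""Flat key->array weight archives.

Keys follow the layer attribute path (``blocks.4.repmlp.partition_perceptron.
fc.weight``); batch-norm running statistics are stored alongside the
trainable arrays with ``.running_mean`` / ``.running_var`` suffixes.
Archives are NumPy ``.npz`` containers; partition ordering inside RepMLP
weights is row-major over the partition grid (see :mod:`mobilerepmlp.repmlp`).
"""

from __future__ import annotations

import numpy as np

from .nn import BatchNorm2d, Layer, Param

__all__ = ["state_dict", "load_state_dict", "save_weights", "load_weights"]


def _walk(layer: Layer, prefix: str, out: dict) -> None:
    for name, value in vars(layer).items():
        key = f"{prefix}{name}"
        if isinstance(value, Param):
            out[key] = value.data
        elif isinstance(value, BatchNorm2d):
            _walk(value, f"{key}.", out)
            out[f"{key}.running_mean"] = value.running_mean
            out[f"{key}.running_var"] = value.running_var
        elif isinstance(value, Layer):
            _walk(value, f"{key}.", out)
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                if isinstance(item, Layer):
                    _walk(item, f"{key}.{i}.", out)
                    if isinstance(item, BatchNorm2d):
                        out[f"{key}.{i}.running_mean"] = item.running_mean
                        out[f"{key}.{i}.running_var"] = item.running_var


def state_dict(model: Layer) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    _walk(model, "", out)
    return out


def load_state_dict(model: Layer, state: dict[str, np.ndarray]) -> None:
    current = _index(model)
    missing = set(current) - set(state)
    extra = set(state) - set(current)
    if missing or extra:
        raise KeyError(f"archive mismatch: missing {sorted(missing)[:5]}, "
                       f"unexpected {sorted(extra)[:5]}")
    for key, target in current.items():
        arr = np.asarray(state[key], dtype=target[0].dtype)
        if arr.shape != target[0].shape:
            raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {target[0].shape}")
        obj, attr = target[1]
        if isinstance(obj, Param):
            obj.data = arr.copy()
        else:
            setattr(obj, attr, arr.copy())


def _index(model: Layer) -> dict:
    """key -> ((array, (owner, attr)) for every storable array."""
    out = {}

    def walk(layer, prefix):
        for name, value in vars(layer).items():
            key = f"{prefix}{name}"
            if isinstance(value, Param):
                out[key] = (value.data, (value, "data"))
            elif isinstance(value, BatchNorm2d):
                walk(value, f"{key}.")
                out[f"{key}.running_mean"] = (value.running_mean, (value, "running_mean"))
                out[f"{key}.running_var"] = (value.running_var, (value, "running_var"))
            elif isinstance(value, Layer):
                walk(value, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Layer):
                        walk(item, f"{key}.{i}.")
                        if isinstance(item, BatchNorm2d):
                            out[f"{key}.{i}.running_mean"] = (item.running_mean, (item, "running_mean"))
                            out[f"{key}.{i}.running_var"] = (item.running_var, (item, "running_var"))

    walk(model, "")
    return out


def save_weights(model: Layer, path) -> None:
    np.savez(path, **state_dict(model))


def load_weights(model: Layer, path) -> None:
    with np.load(path) as data:
        load_state_dict(model, dict(data))
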