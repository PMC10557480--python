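"""Synthetic leaf-disease image generator, augmentation and manifest logic.

Emulates PlantVillage-style photographs — a single leaf on a plain
background, photographed top-down — across 25 classes (5 crops x 5 health
states).  Each class is parameterised by leaf colour, lesion colour, lesion
count and lesion geometry, so classes are cleanly separable by colour/texture
statistics while sharing the leaf-on-background layout of the real data.
The generator is deterministic: identical ``(class model, seed)`` produce
byte-identical images.

The manifest machinery mirrors the usual imbalanced-field-data workflow:
a stratified train/test split of the originals, then per-class augmentation
(flip / mirror / rotate / brightness / contrast / noise) that pads every
class's split to a target count.  Augmented records always derive from an
original in the *same* split, so augmentation can never leak test content
into training or vice versa.

``PLANTVILLAGE_TABLE`` carries the published per-class original/train/test
counts of the 25-class PlantVillage subset used for calibration arithmetic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LeafClassModel",
    "default_classes",
    "generate_leaf_image",
    "AugmentOp",
    "augment",
    "make_manifest",
    "split_dataset",
    "balance_by_augmentation",
    "render_manifest",
    "load_arrays",
    "PLANTVILLAGE_TABLE",
    "PLANTVILLAGE_CLASSES",
]

# (class name, originals, train target, test target)
PLANTVILLAGE_TABLE: tuple[tuple[str, int, int, int], ...] = (
    ("Apple scab", 630, 1512, 437),
    ("Apple black rot", 621, 1491, 418),
    ("Apple rust", 275, 1510, 416),
    ("Apple healthy", 1645, 1495, 404),
    ("Corn gray spot", 513, 1505, 408),
    ("Corn rust", 1192, 1502, 409),
    ("Corn healthy", 1162, 1501, 402),
    ("Corn leaf blight", 985, 1506, 394),
    ("Grape black rot", 1180, 1500, 436),
    ("Grape black measles", 1383, 1507, 424),
    ("Grape healthy", 423, 1508, 402),
    ("Grape leaf blight", 1076, 1506, 415),
    ("Potato early blight", 1000, 1500, 400),
    ("Potato healthy", 152, 1464, 420),
    ("Potato late blight", 1000, 1500, 400),
    ("Tomato health", 1591, 1503, 406),
    ("Tomato spot blight", 1000, 1517, 401),
    ("Tomato two spotted spider mite", 1676, 1506, 405),
    ("Tomato late blight", 1909, 1528, 401),
    ("Tomato leaf mold", 952, 1502, 380),
    ("Tomato bacterial spot", 2127, 1500, 425),
    ("Tomato target spot", 1404, 1514, 487),
    ("Tomato early blight", 1000, 1500, 425),
    ("Tomato mosaic virus", 373, 1495, 444),
    ("Tomato yellow leaf", 5375, 1500, 400),
)

PLANTVILLAGE_CLASSES = tuple(row[0] for row in PLANTVILLAGE_TABLE)


@dataclass(frozen=True)
class LeafClassModel:
    """Appearance parameters of one disease class."""

    class_id: int
    name: str = ""
    leaf_color: tuple[float, float, float] = (60.0, 140.0, 55.0)
    leaf_color_jitter: float = 4.0
    lesion_color: tuple[float, float, float] = (120.0, 80.0, 30.0)
    lesion_count_range: tuple[int, int] = (0, 0)
    lesion_radius_range: tuple[float, float] = (0.04, 0.1)  # fraction of size
    lesion_aspect: float = 1.5
    lesion_softness: float = 0.35
    background_color: tuple[float, float, float] = (205.0, 205.0, 200.0)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


_CROPS = ("apple", "corn", "grape", "potato", "tomato")
_CROP_LEAF = {
    "apple": (58.0, 136.0, 52.0),
    "corn": (95.0, 158.0, 60.0),
    "grape": (52.0, 128.0, 58.0),
    "potato": (70.0, 150.0, 66.0),
    "tomato": (64.0, 146.0, 50.0),
}
# disease states: healthy + four lesion syndromes with distinct colour/shape
_DISEASES = (
    ("healthy", None, (0, 0)),
    ("brown_spot", (124.0, 70.0, 28.0), (6, 12)),
    ("rust", (215.0, 130.0, 25.0), (14, 26)),
    ("blight", (70.0, 48.0, 36.0), (3, 6)),
    ("mosaic", (215.0, 205.0, 80.0), (8, 16)),
)


def default_classes(num_classes: int = 25) -> list[LeafClassModel]:
    """The default label space: crops x disease syndromes, row-major.

    Diseased classes also shift the overall leaf colour toward chlorosis,
    proportional to the disease index, as real infections do.
    """
    models = []
    for cid in range(num_classes):
        crop = _CROPS[(cid // len(_DISEASES)) % len(_CROPS)]
        dname, lesion_color, count = _DISEASES[cid % len(_DISEASES)]
        r, g, b = _CROP_LEAF[crop]
        sev = cid % len(_DISEASES)
        leaf = (r + 26.0 * sev, g - 14.0 * sev, b + 5.0 * sev)
        radius = (0.04 + 0.012 * sev, 0.09 + 0.018 * sev)
        models.append(LeafClassModel(
            class_id=cid,
            name=f"{crop}_{dname}",
            leaf_color=leaf,
            lesion_color=lesion_color or (0.0, 0.0, 0.0),
            lesion_count_range=count,
            lesion_radius_range=radius,
            lesion_aspect=1.2 + 0.3 * sev,
        ))
    return models


def generate_leaf_image(cls: LeafClassModel, seed: int, size: int = 224) -> np.ndarray:
    """Render one leaf photo as a ``(size, size, 3)`` uint8 RGB array.

    Row-major coordinates, origin top-left, RGB channel order.  Deterministic
    in ``(cls, seed)``.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(np.random.SeedSequence([cls.class_id, seed & 0x7FFFFFFF]))
    img = np.empty((size, size, 3), dtype=np.float64)
    img[...] = np.asarray(cls.background_color) + rng.normal(0, 2.0, size=(size, size, 3))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    ay = size * rng.uniform(0.32, 0.42)
    ax = size * rng.uniform(0.22, 0.32)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    leaf_d = (u / ax) ** 2 + (v / ay) ** 2
    leaf_mask = leaf_d <= 1.0

    leaf_col = np.asarray(cls.leaf_color) + rng.normal(0, cls.leaf_color_jitter, 3)
    shading = 1.0 + 0.15 * np.cos(3.0 * np.arctan2(v, u + 1e-9)) * np.sqrt(np.clip(leaf_d, 0, 1))
    leaf_rgb = leaf_col[None, None, :] * shading[:, :, None]
    vein = (np.abs(v) < size * 0.006) & leaf_mask
    img[leaf_mask] = leaf_rgb[leaf_mask]
    img[vein] = leaf_col * 0.8

    lo, hi = cls.lesion_count_range
    n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    for _ in range(n_lesions):
        # rejection-sample a centre inside the leaf
        for _try in range(50):
            ly = rng.uniform(cy - ay, cy + ay)
            lx = rng.uniform(cx - ax, cx + ax)
            uu = (lx - cx) * ct + (ly - cy) * st
            vv = -(lx - cx) * st + (ly - cy) * ct
            if (uu / ax) ** 2 + (vv / ay) ** 2 <= 0.85:
                break
        r1 = size * rng.uniform(*cls.lesion_radius_range)
        r2 = r1 * rng.uniform(1.0, cls.lesion_aspect)
        phi = rng.uniform(0, np.pi)
        cp, sp = np.cos(phi), np.sin(phi)
        du = (xx - lx) * cp + (yy - ly) * sp
        dv = -(xx - lx) * sp + (yy - ly) * cp
        d = (du / r1) ** 2 + (dv / r2) ** 2
        alpha = np.clip((1.0 - d) / cls.lesion_softness, 0.0, 1.0) * leaf_mask
        col = np.asarray(cls.lesion_color) + rng.normal(0, 6.0, 3)
        img = img * (1 - alpha[:, :, None]) + col[None, None, :] * alpha[:, :, None]

    img += rng.normal(0, 2.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_OP_KINDS = ("flip", "mirror", "rotate", "brightness", "contrast", "noise")


@dataclass(frozen=True)
class AugmentOp:
    """One deterministic augmentation step."""

    kind: str
    magnitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _OP_KINDS:
            raise ValueError(f"unknown augment op {self.kind!r}")


def augment(image: np.ndarray, ops: list[AugmentOp]) -> np.ndarray:
    """Apply ``ops`` in order; same shape/dtype; deterministic given seeds.

    * flip — upside-down (involution)
    * mirror — left-right (involution)
    * rotate — ``magnitude`` quarter turns counter-clockwise
    * brightness — multiply by ``magnitude`` (1.0 is identity)
    * contrast — scale deviation from the mean by ``magnitude``
    * noise — add Gaussian noise with sigma ``magnitude`` (gray levels)
    """
    out = image.astype(np.float64)
    for op in ops:
        if op.kind == "flip":
            out = out[::-1, :, :]
        elif op.kind == "mirror":
            out = out[:, ::-1, :]
        elif op.kind == "rotate":
            out = np.rot90(out, k=int(op.magnitude) % 4, axes=(0, 1))
        elif op.kind == "brightness":
            out = out * op.magnitude
        elif op.kind == "contrast":
            mean = out.mean(axis=(0, 1), keepdims=True)
            out = (out - mean) * op.magnitude + mean
        elif op.kind == "noise":
            rng = np.random.default_rng(op.seed)
            out = out + rng.normal(0, op.magnitude, size=out.shape)
    return np.clip(out, 0, 255).astype(image.dtype)


def sample_ops(rng: np.random.Generator) -> list[AugmentOp]:
    """Random augmentation recipe: 1-3 ops drawn from the op set."""
    n = int(rng.integers(1, 4))
    kinds = rng.choice(_OP_KINDS, size=n, replace=False)
    ops = []
    for kind in kinds:
        if kind == "rotate":
            mag = float(rng.integers(1, 4))
        elif kind == "brightness":
            mag = float(rng.uniform(0.8, 1.2))
        elif kind == "contrast":
            mag = float(rng.uniform(0.8, 1.25))
        elif kind == "noise":
            mag = float(rng.uniform(4.0, 10.0))
        else:
            mag = 1.0
        ops.append(AugmentOp(kind, mag, int(rng.integers(0, 2**31 - 1))))
    return ops


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

_COLUMNS = ["path", "class_id", "split", "provenance", "source", "ops", "seed"]


def make_manifest(per_class_counts, seed: int = 0) -> pd.DataFrame:
    """Manifest of original records: ``per_class_counts[c]`` images for class c.

    Paths are virtual until :func:`render_manifest` writes the PNGs; each
    record carries the generation seed, so the manifest fully determines the
    image bytes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cid, count in enumerate(per_class_counts):
        for i in range(count):
            rows.append({
                "path": f"class{cid:02d}/orig_{i:05d}.png",
                "class_id": cid,
                "split": "unassigned",
                "provenance": "original",
                "source": "",
                "ops": "",
                "seed": int(rng.integers(0, 2**31 - 1)),
            })
    return pd.DataFrame(rows, columns=_COLUMNS)


def split_dataset(manifest: pd.DataFrame, ratio: tuple[int, int] = (4, 1),
                  seed: int = 0) -> pd.DataFrame:
    """Stratified train/test assignment of the original records.

    Per class, a fraction ``ratio[0]/(ratio[0]+ratio[1])`` (rounded) goes to
    train.  Classes with fewer than 2 originals are warned about and assigned
    entirely to train.  Deterministic given ``seed``.
    """
    train_frac = ratio[0] / (ratio[0] + ratio[1])
    out = manifest.copy()
    rng = np.random.default_rng(seed)
    for cid, idx in out.groupby("class_id").groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            warnings.warn(f"class {cid} has < 2 originals; assigning all to train")
            out.loc[idx, "split"] = "train"
            continue
        perm = rng.permutation(len(idx))
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        out.loc[idx[perm[:n_train]], "split"] = "train"
        out.loc[idx[perm[n_train:]], "split"] = "test"
    return out


def balance_by_augmentation(manifest: pd.DataFrame, per_class_target,
                            seed: int = 0, split: str = "train") -> pd.DataFrame:
    """Pad every class's ``split`` up to its target count with augmented copies.

    ``per_class_target`` is an int (flat target) or a sequence indexed by
    class id.  New records reference a randomly chosen original *of the same
    split* and carry the op recipe and seeds, so they are reproducible and
    leakage-free by construction.  A class already above its target is
    randomly subsampled down to it (augmented records dropped first), so the
    balanced split hits the targets exactly from either direction.
    """
    out = manifest.copy()
    rng = np.random.default_rng(seed)
    classes = sorted(out["class_id"].unique())
    new_rows = []
    drop: list = []
    for cid in classes:
        target = per_class_target if np.isscalar(per_class_target) else per_class_target[cid]
        sub = out[(out["class_id"] == cid) & (out["split"] == split)]
        originals = sub[sub["provenance"] == "original"]
        if len(originals) == 0:
            raise ValueError(f"class {cid} has no original records in split {split!r}")
        current = len(sub)
        if target < current:
            # drop augmented records first, then originals, at random
            aug_idx = sub.index[sub["provenance"] == "augmented"].to_numpy()
            orig_idx = sub.index[sub["provenance"] == "original"].to_numpy()
            surplus = current - target
            pool = np.concatenate([rng.permutation(aug_idx), rng.permutation(orig_idx)])
            drop.extend(pool[:surplus].tolist())
            continue
        for j in range(target - current):
            src = originals.iloc[int(rng.integers(0, len(originals)))]
            ops = sample_ops(rng)
            new_rows.append({
                "path": f"class{cid:02d}/aug_{split}_{j:05d}.png",
                "class_id": cid,
                "split": split,
                "provenance": "augmented",
                "source": src["path"],
                "ops": json.dumps([[o.kind, o.magnitude, o.seed] for o in ops]),
                "seed": int(src["seed"]),
            })
    if drop:
        out = out.drop(index=drop)
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows, columns=_COLUMNS)], ignore_index=True)
    return out.reset_index(drop=True)


def _render_record(row, models, size):
    img = generate_leaf_image(models[row["class_id"]], int(row["seed"]), size=size)
    if row["provenance"] == "augmented":
        ops = [AugmentOp(k, m, int(s)) for k, m, s in json.loads(row["ops"])]
        img = augment(img, ops)
    return img


def render_manifest(manifest: pd.DataFrame, out_dir, models=None, size: int = 224) -> None:
    """Write every manifest record as a PNG under ``out_dir``."""
    from pathlib import Path
    from PIL import Image

    models = models or default_classes(int(manifest["class_id"].max()) + 1)
    out_dir = Path(out_dir)
    for _, row in manifest.iterrows():
        img = _render_record(row, models, size)
        p = out_dir / row["path"]
        p.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(p)


def load_arrays(manifest: pd.DataFrame, split: str, models=None, size: int = 224):
    """Materialise a split in memory as ``(X, y)``.

    ``X`` is ``(N, 3, size, size)`` float32 scaled to [0, 1]; ``y`` is int64.
    Rendering is in-memory (no files), deterministic from the manifest.
    """
    models = models or default_classes(int(manifest["class_id"].max()) + 1)
    sub = manifest[manifest["split"] == split]
    xs, ys = [], []
    for _, row in sub.iterrows():
        img = _render_record(row, models, size)
        xs.append(img.transpose(2, 0, 1).astype(np.float32) / 255.0)
        ys.append(int(row["class_id"]))
    return np.stack(xs), np.asarray(ys, dtype=np.int64)
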