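"""Synthetic leaf data: generator determinism, augmentation, splits, balancing."""

import numpy as np
import pandas as pd
import pytest

from mobilerepmlp.synthetic import (
    PLANTVILLAGE_TABLE,
    AugmentOp,
    augment,
    balance_by_augmentation,
    default_classes,
    generate_leaf_image,
    load_arrays,
    make_manifest,
    split_dataset,
)


class TestGenerator:
    def test_deterministic_bytes(self):
        cls = default_classes(4)[2]
        a = generate_leaf_image(cls, seed=7)
        b = generate_leaf_image(cls, seed=7)
        assert np.array_equal(a, b)
        c = generate_leaf_image(cls, seed=8)
        assert not np.array_equal(a, c)

    def test_shape_and_range(self):
        img = generate_leaf_image(default_classes(1)[0], seed=0)
        assert img.shape == (224, 224, 3)
        assert img.dtype == np.uint8

    def test_distinct_classes_have_distinct_parameters(self):
        models = default_classes(25)
        keys = {(m.leaf_color, m.lesion_color, m.lesion_count_range) for m in models}
        assert len(keys) == 25

    def test_size_floor(self):
        with pytest.raises(ValueError):
            generate_leaf_image(default_classes(1)[0], seed=0, size=16)

    def test_linear_probe_beats_chance_on_25_classes(self):
        """Raw-pixel linear probe on the full label space must exceed 3x chance,
        guaranteeing the downstream smoke trainings have signal to find."""
        from sklearn.linear_model import LogisticRegression

        manifest = make_manifest([16] * 25, seed=0)
        manifest = split_dataset(manifest, (3, 1), seed=0)
        X, y = load_arrays(manifest, "train", size=32)
        Xt, yt = load_arrays(manifest, "test", size=32)
        clf = LogisticRegression(max_iter=3000).fit(X.reshape(len(X), -1), y)
        acc = clf.score(Xt.reshape(len(Xt), -1), yt)
        assert acc > 3 / 25


class TestAugment:
    def test_flip_mirror_involutions(self, rng):
        img = generate_leaf_image(default_classes(2)[1], seed=3, size=64)
        for kind in ("flip", "mirror"):
            op = AugmentOp(kind)
            assert np.array_equal(augment(augment(img, [op]), [op]), img)

    def test_neutral_brightness_identity(self):
        img = generate_leaf_image(default_classes(1)[0], seed=1, size=64)
        assert np.array_equal(augment(img, [AugmentOp("brightness", 1.0)]), img)

    def test_rotation_four_times_identity(self):
        img = generate_leaf_image(default_classes(1)[0], seed=1, size=64)
        out = img
        for _ in range(4):
            out = augment(out, [AugmentOp("rotate", 1)])
        assert np.array_equal(out, img)

    def test_noise_changes_pixels_but_preserves_mean(self):
        img = generate_leaf_image(default_classes(2)[1], seed=5, size=64)
        changed, dmean = [], []
        for seed in range(100):
            out = augment(img, [AugmentOp("noise", 6.0, seed)])
            changed.append((out != img).mean())
            dmean.append(abs(out.mean() - img.mean()))
        assert min(changed) >= 0.01
        assert max(dmean) < 5.0

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            AugmentOp("shear")


class TestSplit:
    def test_flat_100_originals_gives_80_20(self):
        manifest = make_manifest([100], seed=0)
        out = split_dataset(manifest, (4, 1), seed=0)
        assert (out["split"] == "train").sum() == 80
        assert (out["split"] == "test").sum() == 20

    def test_deterministic(self):
        manifest = make_manifest([30, 40], seed=1)
        a = split_dataset(manifest, (4, 1), seed=9)
        b = split_dataset(manifest, (4, 1), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_per_class_proportions(self, rng):
        counts = list(rng.integers(10, 60, size=25))
        manifest = make_manifest(counts, seed=2)
        out = split_dataset(manifest, (4, 1), seed=2)
        for cid, n in enumerate(counts):
            n_train = int(((out["class_id"] == cid) & (out["split"] == "train")).sum())
            assert abs(n_train - 0.8 * n) <= 1

    def test_tiny_class_warns_and_goes_to_train(self):
        manifest = make_manifest([1, 10], seed=0)
        with pytest.warns(UserWarning):
            out = split_dataset(manifest, (4, 1), seed=0)
        assert (out.loc[out["class_id"] == 0, "split"] == "train").all()


class TestBalance:
    def _split_manifest(self, counts, seed=0):
        return split_dataset(make_manifest(counts, seed=seed), (4, 1), seed=seed)

    def test_target_arithmetic(self):
        manifest = make_manifest([10, 4], seed=0)
        manifest["split"] = "train"
        out = balance_by_augmentation(manifest, 12, seed=0)
        counts = out[out["split"] == "train"].groupby("class_id").size()
        assert counts.tolist() == [12, 12]
        added = out[out["provenance"] == "augmented"].groupby("class_id").size()
        assert added.tolist() == [2, 8]

    def test_published_training_targets_total(self):
        """Scaled-down per-class originals balanced to the published per-class
        training targets reproduce the published total of 37,572 records."""
        train_targets = [row[2] for row in PLANTVILLAGE_TABLE]
        # split 4:1 per class on the published original counts
        originals = [row[1] for row in PLANTVILLAGE_TABLE]
        manifest = self._split_manifest(originals)
        out = balance_by_augmentation(manifest, train_targets, seed=0)
        assert int((out["split"] == "train").sum()) == 37_572

    def test_over_target_class_is_subsampled(self):
        manifest = make_manifest([10], seed=0)
        manifest["split"] = "train"
        out = balance_by_augmentation(manifest, 5, seed=0)
        assert len(out) == 5
        assert (out["provenance"] == "original").all()

    @pytest.mark.parametrize("seed", range(10))
    def test_no_cross_split_leakage(self, seed):
        """No augmented record may derive from an original in the other split."""
        rng = np.random.default_rng(seed)
        counts = list(rng.integers(5, 25, size=6))
        manifest = self._split_manifest(counts, seed=seed)
        out = balance_by_augmentation(manifest, 30, seed=seed, split="train")
        out = balance_by_augmentation(out, 12, seed=seed + 1, split="test")
        src_split = out.set_index("path")["split"]
        aug = out[out["provenance"] == "augmented"]
        for _, row in aug.iterrows():
            assert src_split[row["source"]] == row["split"]

    def test_manifest_roundtrip_determinism(self, tmp_path):
        """manifest -> csv -> manifest preserves rendered image bytes."""
        manifest = self._split_manifest([6, 6])
        manifest = balance_by_augmentation(manifest, 8, seed=3)
        p = tmp_path / "m.csv"
        manifest.to_csv(p, index=False)
        back = pd.read_csv(p, keep_default_na=False)
        X1, y1 = load_arrays(manifest, "train", size=32)
        X2, y2 = load_arrays(back, "train", size=32)
        assert np.array_equal(X1, X2) and np.array_equal(y1, y2)
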