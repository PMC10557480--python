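"""Generate a synthetic leaf-disease dataset: split, balance, inspect.

The generator emulates single-leaf-on-plain-background photographs for 25
classes (5 crops x 5 health states).  The manifest records every original
and augmented image with its seeds and op recipe, so the dataset is fully
reproducible from the CSV alone.
"""

import numpy as np

from mobilerepmlp.synthetic import (
    balance_by_augmentation,
    default_classes,
    generate_leaf_image,
    make_manifest,
    split_dataset,
)

# imbalanced originals, as field data always is
rng = np.random.default_rng(0)
counts = rng.integers(10, 60, size=25).tolist()
manifest = make_manifest(counts, seed=0)
manifest = split_dataset(manifest, ratio=(4, 1), seed=0)
print("train/test originals:",
      int((manifest['split'] == 'train').sum()), "/",
      int((manifest['split'] == 'test').sum()))

balanced = balance_by_augmentation(manifest, per_class_target=60, seed=0)
per_class = balanced[balanced["split"] == "train"].groupby("class_id").size()
print("after balancing, per-class train counts:",
      sorted(per_class.unique().tolist()))
aug = balanced[balanced["provenance"] == "augmented"]
print(f"augmented records: {len(aug)} "
      f"(each references an original of the same split -> no leakage)")

img = generate_leaf_image(default_classes(25)[6], seed=123)
print("one rendered image:", img.shape, img.dtype,
      "value range", (int(img.min()), int(img.max())))
# Identical (class, seed) always produce byte-identical pixels.
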