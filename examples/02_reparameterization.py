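"""Fold a RepMLP block's training-time conv/BN branches into its FC weights.

The deployed block computes the identical function with a single grouped
matmul per partition: the printed max-abs difference is float32 round-off,
and the deployed form carries no convolution branches at all.
"""

import numpy as np

from mobilerepmlp import RepMLP, RepMLPSpec, reparameterize
from mobilerepmlp.metrics import bench_inference

spec = RepMLPSpec(in_channels=16, height=14, width=14, part_h=7, part_w=7)
block = RepMLP(spec, rng=np.random.default_rng(0))

# give the batch norms non-trivial statistics, as training would
rng = np.random.default_rng(1)
for bn in [block.partition_perceptron.bn, *block.local_perceptron.bns]:
    bn.running_mean = rng.normal(0, 1, bn.channels).astype(np.float32)
    bn.running_var = rng.uniform(0.5, 2, bn.channels).astype(np.float32)

deployed = reparameterize(block)
x = rng.normal(size=(4, 16, 14, 14)).astype(np.float32)
diff = np.abs(block.forward(x) - deployed.forward(x)).max()

print(f"max |training - deployed| on random input : {diff:.2e}")
print(f"conv branches in deployed form            : {deployed.local_perceptron}")
t_train = bench_inference(block, (16, 14, 14), n_images=8, repeats=3)
t_dep = bench_inference(deployed, (16, 14, 14), n_images=8, repeats=3)
print(f"latency training form : {t_train['ms_per_image']:.3f} ms/image")
print(f"latency deployed form : {t_dep['ms_per_image']:.3f} ms/image")
# A diff around 1e-6 means the fold is exact to float32 precision; the
# deployed form is the one to ship on edge devices.
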