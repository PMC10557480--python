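"""Structural re-parameterization: fold conv+BN side paths into FC weights.

A trained RepMLP block evaluates, per partition ``x``,

    BN3(FC3(vec(x))) + sum_k BN_k(conv_k(x))

All terms are affine in ``x`` at inference time (BN frozen on running
statistics), so the whole expression collapses into one grouped FC with a
bias.  The converter

1. folds each branch's BN into its convolution (scale/shift of the kernel),
2. converts each convolution into the equivalent FC matrix by probing it
   with the identity basis of a partition (each basis image produces one
   matrix column),
3. folds BN3 into FC3 (row scaling plus a bias), and
4. sums everything into a single weight matrix and bias.

The deployed block is mathematically identical to the training block — the
package's equivalence tests hold it to 1e-5 max-abs on random inputs — but
runs a single matmul per partition.  All folding arithmetic is done in
float64.
"""

from __future__ import annotations

import copy

import numpy as np

from .nn import BatchNorm2d, GroupedLinear
from .repmlp import RepMLP, RepMLPSpec

__all__ = [
    "fuse_bn_into_conv",
    "conv_to_fc",
    "reparameterize",
]


def fuse_bn_into_conv(weight: np.ndarray, bias: np.ndarray | None, bn: BatchNorm2d):
    """Fold an inference-mode BN into the preceding convolution.

    Returns ``(W', b')`` with ``W'_c = gamma_c W_c / sqrt(var_c + eps)`` and
    ``b'_c = beta_c + gamma_c (b_c - mean_c) / sqrt(var_c + eps)``.
    """
    w = weight.astype(np.float64)
    var = bn.running_var.astype(np.float64)
    if np.any(var + bn.eps <= 0):
        raise FloatingPointError("non-positive variance in BN fusion")
    inv = bn.gamma.data.astype(np.float64) / np.sqrt(var + bn.eps)
    b = np.zeros(w.shape[0], dtype=np.float64) if bias is None else bias.astype(np.float64)
    w_fused = w * inv[:, None, None, None]
    b_fused = bn.beta.data.astype(np.float64) + (b - bn.running_mean.astype(np.float64)) * inv
    return w_fused, b_fused


def conv_to_fc(weight: np.ndarray, h: int, w: int, groups: int) -> np.ndarray:
    """Equivalent block-diagonal FC blocks for a shape-preserving convolution.

    ``weight`` has shape ``(o, C/g, K, K)``.  Returns an array of per-group
    matrices ``(g, (o/g)*h*w, (C/g)*h*w)`` such that multiplying the
    channel-major flattened partition reproduces the padded convolution.
    The construction probes the convolution with the identity basis, so it is
    exact by definition for every input.
    """
    o, cig, k, _ = weight.shape
    g = groups
    cog = o // g
    n_in = cig * h * w
    blocks = np.zeros((g, cog * h * w, n_in), dtype=np.float64)
    # one probe batch per group; groups share geometry so probe once per group slice
    eye = np.eye(n_in, dtype=np.float64).reshape(n_in, cig, h, w)
    for gi in range(g):
        out = _conv_probe(eye, weight[gi * cog : (gi + 1) * cog], k)
        blocks[gi] = out.reshape(n_in, cog * h * w).T
    return blocks


def _conv_probe(x: np.ndarray, w: np.ndarray, k: int) -> np.ndarray:
    """Direct float64 padded convolution used by the probe construction."""
    n, c, h, ww = x.shape
    o = w.shape[0]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    out = np.zeros((n, o, h, ww), dtype=np.float64)
    for ki in range(k):
        for kj in range(k):
            patch = xp[:, :, ki : ki + h, kj : kj + ww]
            out += np.einsum("nchw,oc->nohw", patch, w[:, :, ki, kj], optimize=True)
    return out


def _fold_bn_into_fc(fc: GroupedLinear, bn: BatchNorm2d, spec: RepMLPSpec):
    """Fold the partition perceptron's BN into its grouped FC.

    Output feature ``r`` of the FC corresponds to channel ``r // (h*w)``, so
    BN acts as a per-row scale and shift.
    """
    hw = spec.part_h * spec.part_w
    inv = bn.gamma.data.astype(np.float64) / np.sqrt(bn.running_var.astype(np.float64) + bn.eps)
    shift = bn.beta.data.astype(np.float64) - bn.running_mean.astype(np.float64) * inv
    cog = spec.out_channels // spec.groups
    # rows within a group block: (cog, hw) channel-major
    row_scale = np.repeat(inv.reshape(spec.groups, cog), hw, axis=1)  # (g, cog*hw)
    row_shift = np.repeat(shift.reshape(spec.groups, cog), hw, axis=1)
    w = fc.weight.data.astype(np.float64) * row_scale[:, :, None]
    b = row_shift.reshape(-1)
    return w, b


def reparameterize(block: RepMLP) -> RepMLP:
    """Convert a training-form RepMLP into its deployed form.

    The returned block has no convolutional branches and no BN; its grouped
    FC (now with bias) reproduces the training block's output to float32
    round-off.  The global perceptron is purely FC already and is copied
    unchanged.
    """
    if block.deployed:
        raise ValueError("block is already in deployed form")
    spec = block.spec
    hw = spec.part_h * spec.part_w
    fc_w, fc_b = _fold_bn_into_fc(block.partition_perceptron.fc,
                                  block.partition_perceptron.bn, spec)
    local = block.local_perceptron
    for conv, bn in zip(local.convs, local.bns):
        w_f, b_f = fuse_bn_into_conv(conv.weight.data, None, bn)
        blocks = conv_to_fc(w_f, spec.part_h, spec.part_w, spec.groups)
        fc_w = fc_w + blocks
        fc_b = fc_b + np.repeat(b_f, hw)

    deployed = RepMLP(spec, deployed=True)
    deployed.global_perceptron = copy.deepcopy(block.global_perceptron)
    deployed.partition_perceptron.fc.weight.data = fc_w.astype(np.float32)
    deployed.partition_perceptron.fc.bias.data = fc_b.astype(np.float32)
    return deployed
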