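"""RepMLP block: partitioning, the three perceptrons, and block forward."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobilerepmlp.repmlp import (
    GlobalPerceptron,
    LocalPerceptron,
    PartitionPerceptron,
    RepMLP,
    RepMLPSpec,
    partition_merge,
    partition_split,
)

from conftest import direct_conv2d, randomize_bn_stats


class TestPartitioning:
    def test_4x4_with_2x2_partitions(self, rng):
        x = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        parts = partition_split(x, 2, 2)
        assert parts.shape == (4, 1, 2, 2)
        # row-major partition order
        np.testing.assert_array_equal(parts[0, 0], x[0, 0, :2, :2])
        np.testing.assert_array_equal(parts[1, 0], x[0, 0, :2, 2:])
        np.testing.assert_array_equal(parts[2, 0], x[0, 0, 2:, :2])
        np.testing.assert_array_equal(x, partition_merge(parts, 1, 4, 4))

    def test_stage_shape_arithmetic(self, rng):
        x = rng.normal(size=(1, 24, 14, 14)).astype(np.float32)
        assert partition_split(x, 7, 7).shape == (4, 24, 7, 7)

    def test_non_divisible_rejected(self, rng):
        with pytest.raises(ValueError):
            partition_split(np.zeros((1, 1, 5, 4), np.float32), 2, 2)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(1, 3), st.integers(1, 4), st.sampled_from([(4, 2), (6, 3), (8, 4), (7, 7)]),
           st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, n, c, hw, seed):
        H, h = hw
        x = np.random.default_rng(seed).normal(size=(n, c, H, H)).astype(np.float32)
        merged = partition_merge(partition_split(x, h, h), n, H, H)
        assert np.array_equal(merged, x)  # bit-exact


class TestGlobalPerceptron:
    def test_zero_fc_weights_identity(self, rng):
        gp = GlobalPerceptron(6, 2, rng=rng)
        gp.fc1.weight.data[...] = 0
        gp.fc1.bias.data[...] = 0
        gp.fc2.weight.data[...] = 0
        gp.fc2.bias.data[...] = 0
        parts = rng.normal(size=(3, 6, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(gp.forward(parts), parts, atol=1e-7)

    def test_constant_input_uniform_shift(self, rng):
        """On a constant partition the branch adds FC2(relu(FC1(c))) uniformly."""
        gp = GlobalPerceptron(4, 2, rng=rng)
        c = 1.5
        parts = np.full((1, 4, 3, 3), c, dtype=np.float32)
        pooled = np.full(4, c)
        v = gp.fc2.weight.data @ np.maximum(gp.fc1.weight.data @ pooled + gp.fc1.bias.data, 0) + gp.fc2.bias.data
        expected = parts + v[None, :, None, None].astype(np.float32)
        np.testing.assert_allclose(gp.forward(parts), expected, atol=1e-5)

    def test_shape_preserved(self, rng):
        gp = GlobalPerceptron(8, 4, rng=rng)
        parts = rng.normal(size=(5, 8, 7, 7)).astype(np.float32)
        assert gp.forward(parts).shape == parts.shape


class TestPartitionPerceptron:
    def _spec(self, c=4, h=2, g=2, o=0):
        return RepMLPSpec(c, h * 2, h * 2, h, h, groups=g, out_channels=o,
                          bn_epsilon=0.0)

    def test_identity_weights_identity_bn(self, rng):
        spec = self._spec()
        pp = PartitionPerceptron(spec, rng=rng)
        n = spec.in_channels * spec.part_h * spec.part_w // spec.groups
        pp.fc.weight.data = np.stack([np.eye(n, dtype=np.float32)] * spec.groups)
        parts = rng.normal(size=(3, 4, 2, 2)).astype(np.float32)
        np.testing.assert_allclose(pp.forward(parts), parts, atol=1e-6)

    def test_zero_weights_broadcast_beta(self, rng):
        spec = self._spec()
        pp = PartitionPerceptron(spec, rng=rng)
        pp.fc.weight.data[...] = 0
        pp.bn.beta.data = rng.normal(size=4).astype(np.float32)
        parts = rng.normal(size=(3, 4, 2, 2)).astype(np.float32)
        out = pp.forward(parts)
        np.testing.assert_allclose(out, np.broadcast_to(
            pp.bn.beta.data[None, :, None, None], out.shape), atol=1e-6)

    def test_matches_dense_matmul_oracle(self, rng):
        spec = self._spec(c=6, h=3, g=3)
        pp = PartitionPerceptron(spec, rng=rng)
        randomize_bn_stats(pp, rng)
        parts = rng.normal(size=(2, 6, 3, 3)).astype(np.float32)
        out = pp.forward(parts)
        dense = pp.fc.dense_weight()
        flat = parts.reshape(2, -1) @ dense.T
        y = flat.reshape(2, 6, 3, 3)
        inv = pp.bn.gamma.data / np.sqrt(pp.bn.running_var + pp.bn.eps)
        ref = (y - pp.bn.running_mean[None, :, None, None]) * inv[None, :, None, None] \
            + pp.bn.beta.data[None, :, None, None]
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_out_channels_must_divide_groups(self):
        with pytest.raises(ValueError):
            RepMLPSpec(4, 4, 4, 2, 2, groups=2, out_channels=5)


class TestLocalPerceptron:
    def _spec(self, c=4, h=4, ks=(1, 3)):
        return RepMLPSpec(c, h, h, h, h, groups=c, local_kernels=ks)

    def test_zero_weights_zero_contribution(self, rng):
        lp = LocalPerceptron(self._spec(), rng=rng)
        for conv in lp.convs:
            conv.weight.data[...] = 0
        parts = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        assert np.allclose(lp.forward(parts), 0, atol=1e-7)

    def test_single_scalar_kernel_doubles(self, rng):
        spec = RepMLPSpec(3, 2, 2, 2, 2, groups=3, local_kernels=(1,),
                          bn_epsilon=0.0)
        lp = LocalPerceptron(spec, rng=rng)
        lp.convs[0].weight.data[...] = 2.0
        parts = rng.normal(size=(2, 3, 2, 2)).astype(np.float32)
        np.testing.assert_allclose(lp.forward(parts), 2 * parts, atol=1e-6)

    def test_matches_per_branch_direct_convolution(self, rng):
        spec = RepMLPSpec(4, 6, 6, 6, 6, groups=2, local_kernels=(1, 3, 5))
        lp = LocalPerceptron(spec, rng=rng)
        randomize_bn_stats(lp, rng)
        parts = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)
        ref = np.zeros((2, 4, 6, 6))
        for conv, bn in zip(lp.convs, lp.bns):
            y = direct_conv2d(parts, conv.weight.data, 1, conv.kernel_size // 2, 2)
            inv = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
            ref += (y - bn.running_mean[None, :, None, None]) * inv[None, :, None, None] \
                + bn.beta.data[None, :, None, None]
        np.testing.assert_allclose(lp.forward(parts), ref, atol=1e-4)


class TestRepMLPForward:
    def test_zero_weights_zero_output(self, rng):
        spec = RepMLPSpec(4, 4, 4, 2, 2, groups=2)
        blk = RepMLP(spec, rng=rng)
        for _, p in blk.named_parameters():
            if p.name in ("weight", "bias"):
                p.data[...] = 0
        x = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        assert np.allclose(blk.forward(x), 0, atol=1e-6)

    def test_shape_contract_14x14(self, rng):
        spec = RepMLPSpec(16, 14, 14, 7, 7)
        blk = RepMLP(spec, rng=rng)
        x = rng.normal(size=(1, 16, 14, 14)).astype(np.float32)
        assert blk.forward(x).shape == (1, 16, 14, 14)

    def test_matches_monolithic_oracle(self, rng):
        """Explicit evaluation of all three perceptrons on the raw arrays."""
        spec = RepMLPSpec(4, 6, 6, 3, 3, groups=2, local_kernels=(1, 3))
        blk = RepMLP(spec, rng=rng)
        randomize_bn_stats(blk, rng)
        x = rng.normal(size=(2, 4, 6, 6)).astype(np.float32)

        parts = partition_split(x, 3, 3).astype(np.float64)
        gp = blk.global_perceptron
        pooled = parts.mean(axis=(2, 3))
        hid = np.maximum(pooled @ gp.fc1.weight.data.T + gp.fc1.bias.data, 0)
        parts = parts + (hid @ gp.fc2.weight.data.T + gp.fc2.bias.data)[:, :, None, None]

        dense = blk.partition_perceptron.fc.dense_weight()
        y = (parts.reshape(len(parts), -1) @ dense.T).reshape(parts.shape)
        bn = blk.partition_perceptron.bn
        inv = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
        y = (y - bn.running_mean[None, :, None, None]) * inv[None, :, None, None] \
            + bn.beta.data[None, :, None, None]

        for conv, cbn in zip(blk.local_perceptron.convs, blk.local_perceptron.bns):
            z = direct_conv2d(parts, conv.weight.data, 1, conv.kernel_size // 2, spec.groups)
            cinv = cbn.gamma.data / np.sqrt(cbn.running_var + cbn.eps)
            y = y + (z - cbn.running_mean[None, :, None, None]) * cinv[None, :, None, None] \
                + cbn.beta.data[None, :, None, None]

        ref = partition_merge(y.astype(np.float32), 2, 6, 6)
        np.testing.assert_allclose(blk.forward(x), ref, atol=1e-5)

    def test_affine_superposition(self, rng):
        """At inference the block is affine in x: f(a+b) - f(0) equals
        (f(a) - f(0)) + (f(b) - f(0)), once the global ReLU path is disabled."""
        spec = RepMLPSpec(4, 4, 4, 2, 2, groups=4)
        blk = RepMLP(spec, rng=rng)
        randomize_bn_stats(blk, rng)
        blk.global_perceptron.fc1.weight.data[...] = 0  # removes the only nonlinearity
        a = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
        b = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
        f0 = blk.forward(np.zeros_like(a))
        lhs = blk.forward(a + b) - f0
        rhs = (blk.forward(a) - f0) + (blk.forward(b) - f0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-4)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RepMLPSpec(4, 5, 5, 2, 2)  # not divisible
        with pytest.raises(ValueError):
            RepMLPSpec(4, 4, 4, 2, 2, local_kernels=(7,))
        blk = RepMLP(RepMLPSpec(4, 4, 4, 2, 2))
        with pytest.raises(ValueError):
            blk.forward(np.zeros((1, 5, 4, 4), np.float32))
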