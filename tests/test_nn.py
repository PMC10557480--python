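"""Core layer framework: forward correctness against direct oracles,
backward correctness against independently derived gradients."""

import numpy as np
import pytest

from mobilerepmlp.nn import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    GroupedLinear,
    Linear,
    hardswish,
    relu6,
    softmax_cross_entropy,
)

from conftest import direct_conv2d


@pytest.mark.parametrize("cin,cout,k,stride,pad,groups", [
    (3, 5, 3, 1, 1, 1),
    (4, 6, 3, 2, 1, 2),
    (4, 4, 3, 1, 1, 4),   # depthwise
    (6, 8, 1, 1, 0, 2),   # grouped pointwise
    (2, 3, 5, 2, 2, 1),
])
def test_conv2d_matches_direct_summation(rng, cin, cout, k, stride, pad, groups):
    conv = Conv2d(cin, cout, k, stride=stride, padding=pad, groups=groups,
                  bias=True, rng=rng)
    x = rng.normal(size=(2, cin, 8, 8)).astype(np.float32)
    expected = direct_conv2d(x, conv.weight.data, stride, pad, groups,
                             conv.bias.data)
    out = conv.forward(x)
    assert out.shape == expected.shape
    np.testing.assert_allclose(out, expected, atol=1e-5)


def test_conv2d_rejects_bad_geometry():
    with pytest.raises(ValueError):
        Conv2d(4, 6, 3, groups=4)  # cout not divisible by groups
    with pytest.raises(ValueError):
        Conv2d(4, 4, 0)
    conv = Conv2d(4, 4, 3, padding=1)
    with pytest.raises(ValueError):
        conv.forward(np.zeros((1, 3, 8, 8), dtype=np.float32))


def test_conv2d_gradients_match_reference(rng):
    """dW and dx from backward equal the analytically derived values for a
    linear functional loss sum(out * R)."""
    conv = Conv2d(3, 4, 3, stride=2, padding=1, groups=1, bias=True, rng=rng)
    x = rng.normal(size=(2, 3, 7, 7)).astype(np.float32)
    out = conv.forward(x, training=True)
    R = rng.normal(size=out.shape).astype(np.float32)
    dx = conv.backward(R)
    # reference dW by probing: dL/dW_i = sum(R * d out/d W_i) with conv linear in W
    w = conv.weight.data
    for _ in range(6):
        idx = tuple(int(rng.integers(0, s)) for s in w.shape)
        probe = np.zeros_like(w)
        probe[idx] = 1.0
        dout = direct_conv2d(x, probe, 2, 1, 1)
        ref = float((R * dout).sum())
        assert conv.weight.grad[idx] == pytest.approx(ref, rel=1e-3, abs=1e-4)
    # reference dx by probing inputs
    for _ in range(6):
        idx = tuple(int(rng.integers(0, s)) for s in x.shape)
        xp = x.copy()
        xp[idx] += 1.0
        dout = direct_conv2d(xp, w, 2, 1, 1) - direct_conv2d(x, w, 2, 1, 1)
        ref = float((R * dout).sum())
        assert dx[idx] == pytest.approx(ref, rel=1e-3, abs=1e-4)


def test_batchnorm_two_modes(rng):
    bn = BatchNorm2d(3)
    x = rng.normal(2.0, 3.0, size=(8, 3, 4, 4)).astype(np.float32)
    out = bn.forward(x, training=True)
    # training mode standardises with batch statistics
    assert np.allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-5)
    assert np.allclose(out.std(axis=(0, 2, 3)), 1, atol=1e-3)
    # inference mode uses running statistics: with the default momentum the
    # running mean has moved only a fraction of the way toward the batch mean
    out_eval = bn.forward(x, training=False)
    assert not np.allclose(out_eval, out, atol=1e-2)
    # after many updates on the same batch, the two modes agree (up to the
    # biased/unbiased variance correction)
    for _ in range(200):
        bn.forward(x, training=True)
    np.testing.assert_allclose(bn.forward(x, training=False), out, atol=0.05)


def test_batchnorm_gradients_match_reference(rng):
    """Backward equals the closed-form batch-statistics gradient."""
    bn = BatchNorm2d(4)
    bn.gamma.data = rng.normal(1, 0.3, 4).astype(np.float32)
    x = rng.normal(size=(3, 4, 5, 5)).astype(np.float32)
    out = bn.forward(x, training=True)
    R = rng.normal(size=out.shape).astype(np.float32)
    dx = bn.backward(R)
    x64 = x.astype(np.float64)
    mean = x64.mean(axis=(0, 2, 3), keepdims=True)
    var = x64.var(axis=(0, 2, 3), keepdims=True)
    inv = 1 / np.sqrt(var + bn.eps)
    xhat = (x64 - mean) * inv
    m = x64.shape[0] * x64.shape[2] * x64.shape[3]
    dxhat = R * bn.gamma.data[None, :, None, None]
    ref = inv * (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                 - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
    np.testing.assert_allclose(dx, ref, atol=1e-4)
    np.testing.assert_allclose(bn.gamma.grad, (R * xhat).sum(axis=(0, 2, 3)), rtol=1e-4)
    np.testing.assert_allclose(bn.beta.grad, R.sum(axis=(0, 2, 3)), rtol=1e-4)


def test_grouped_linear_equals_dense_blockdiag(rng):
    gl = GroupedLinear(12, 8, 4, bias=True, rng=rng)
    x = rng.normal(size=(5, 12)).astype(np.float32)
    dense = gl.dense_weight()
    np.testing.assert_allclose(gl.forward(x), x @ dense.T + gl.bias.data, atol=1e-5)


def test_activation_formulas():
    assert hardswish(np.float32(0.0)) == 0.0
    assert hardswish(np.float32(-3.0)) == 0.0
    assert hardswish(np.float32(3.0)) == pytest.approx(3.0)
    assert hardswish(np.float32(100.0)) == pytest.approx(100.0)  # saturates to x
    assert relu6(np.float32(7.0)) == 6.0
    assert relu6(np.float32(-1.0)) == 0.0


def test_avgpool_and_gap(rng):
    x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
    pool = AvgPool2d(2, 2)
    out = pool.forward(x)
    np.testing.assert_allclose(out[0, 0, 0, 0], x[0, 0, :2, :2].mean(), rtol=1e-6)
    assert out.shape == (2, 3, 3, 3)
    gap = GlobalAvgPool().forward(x)
    np.testing.assert_allclose(gap, x.mean(axis=(2, 3)), rtol=1e-6)


def test_softmax_cross_entropy_gradient(rng):
    logits = rng.normal(size=(4, 5)).astype(np.float32)
    y = np.array([0, 3, 2, 1])
    loss, grad = softmax_cross_entropy(logits, y)
    # analytic: (softmax - onehot)/n
    z = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = z / z.sum(axis=1, keepdims=True)
    ref = p.copy()
    ref[np.arange(4), y] -= 1
    np.testing.assert_allclose(grad, ref / 4, atol=1e-6)
    assert loss == pytest.approx(-np.log(p[np.arange(4), y]).mean(), rel=1e-5)
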