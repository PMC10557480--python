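import numpy as np
import pytest

from mobilerepmlp.nn import BatchNorm2d, Layer


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def randomize_bn_stats(layer: Layer, rng: np.random.Generator) -> None:
    """Give every BN non-trivial running statistics and affine parameters so
    that BN folding is exercised with realistic numbers."""
    for value in vars(layer).values():
        if isinstance(value, BatchNorm2d):
            value.running_mean = rng.normal(0, 1, value.channels).astype(np.float32)
            value.running_var = rng.uniform(0.5, 2.0, value.channels).astype(np.float32)
            value.gamma.data = rng.normal(1.0, 0.2, value.channels).astype(np.float32)
            value.beta.data = rng.normal(0.0, 0.2, value.channels).astype(np.float32)
        elif isinstance(value, Layer):
            randomize_bn_stats(value, rng)
        elif isinstance(value, (list, tuple)):
            for item in value:
                if isinstance(item, Layer):
                    randomize_bn_stats(item, rng)


def direct_conv2d(x, weight, stride=1, padding=0, groups=1, bias=None):
    """Brute-force sliding-window convolution oracle (float64, explicit loops)."""
    x = np.asarray(x, dtype=np.float64)
    weight = np.asarray(weight, dtype=np.float64)
    n, c, h, w = x.shape
    o, cig, k, _ = weight.shape
    cog = o // groups
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (x.shape[2] - k) // stride + 1
    wo = (x.shape[3] - k) // stride + 1
    out = np.zeros((n, o, ho, wo))
    for ni in range(n):
        for oi in range(o):
            gi = oi // cog
            for yi in range(ho):
                for xi in range(wo):
                    acc = 0.0
                    for ci in range(cig):
                        cin = gi * cig + ci
                        for ki in range(k):
                            for kj in range(k):
                                acc += (x[ni, cin, yi * stride + ki, xi * stride + kj]
                                        * weight[oi, ci, ki, kj])
                    out[ni, oi, yi, xi] = acc
    if bias is not None:
        out += np.asarray(bias, dtype=np.float64)[None, :, None, None]
    return out
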