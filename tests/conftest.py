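import numpy as np
import pytest

from vesselseg import SyntheticSpec, generate_dataset, generate_sample


def numerical_gradient(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of scalar fn at x (float64)."""
    x = x.astype(np.float64)
    grad = np.zeros_like(x)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad


def naive_conv2d(x, w, stride=1, padding=0, dilation=1):
    """Nested-loop 2-D cross-correlation oracle, NCHW x (F,C,kh,kw)."""
    n, c, h, width = x.shape
    f, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    ow = (width + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((n, f, oh, ow), dtype=np.float64)
    for ni in range(n):
        for fi in range(f):
            for oi in range(oh):
                for oj in range(ow):
                    acc = 0.0
                    for ci in range(c):
                        for ki in range(kh):
                            for kj in range(kw):
                                acc += (
                                    xp[ni, ci, oi * stride + ki * dilation, oj * stride + kj * dilation]
                                    * w[fi, ci, ki, kj]
                                )
                    out[ni, fi, oi, oj] = acc
    return out


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def sample(default_spec):
    return generate_sample(default_spec)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 32x32 train/test sets for fast training smoke tests."""
    spec = SyntheticSpec(height=32, width=32, n_trees=2, seed=3)
    return generate_dataset(spec, 8, 4)
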