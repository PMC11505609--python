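import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, lo=0.3, hi=2.0):
    """Random symmetric positive-definite 3x3 tensor (um^2/ms scale)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    lam = rng.uniform(lo, hi, 3)
    return (Q * lam) @ Q.T


def random_kurtosis_tensor(rng, scale=0.6, n_terms=4):
    """Fully symmetric rank-4 tensor with nonnegative W_app everywhere
    (sum of c * v^(x4) outer products, c >= 0)."""
    W = np.zeros((3, 3, 3, 3))
    for _ in range(n_terms):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        W += rng.uniform(0.2, 1.0) * np.einsum("i,j,k,l->ijkl", v, v, v, v)
    return W * scale
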