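import numpy as np
import pytest

from ckalign import make_fixture


@pytest.fixture(scope="session")
def tiny3class():
    data, meta = make_fixture("tiny3class")
    return data, meta


@pytest.fixture(scope="session")
def xor2class():
    data, meta = make_fixture("xor2class")
    return data, meta


@pytest.fixture(scope="session")
def scale_confounded():
    data, meta = make_fixture("scale-confounded")
    return data, meta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def center_elementwise(K):
    """Independent elementwise double-centering oracle:
    k̄_nn' = k_nn' - mean_n - mean_n' + grand mean, written as loops."""
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    out = np.empty_like(K)
    grand = K.sum() / (n * n)
    for i in range(n):
        for j in range(n):
            out[i, j] = K[i, j] - K[i, :].mean() - K[:, j].mean() + grand
    return out


def cka_bruteforce(Kx, Kl):
    """Frobenius-product CKA oracle on elementwise-centered kernels."""
    A = center_elementwise(Kx)
    B = center_elementwise(Kl)
    num = float(np.sum(A * B))
    return num / np.sqrt(float(np.sum(A * A)) * float(np.sum(B * B)))
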