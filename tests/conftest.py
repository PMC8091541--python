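import numpy as np
import pytest

from modalign import PrimaryModality, SecondaryModality, sample_pairs


def all_pairs(N):
    """Lexicographic list of all unordered index pairs (independent oracle)."""
    return [(n, m) for n in range(N) for m in range(n + 1, N)]


def two_pass_pearson(x, y):
    """Textbook population Pearson correlation, written independently."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).mean()
    sx = np.sqrt(((x - mx) ** 2).mean())
    sy = np.sqrt(((y - my) ** 2).mean())
    return cov / (sx * sy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_numeric_primary(rng):
    X = rng.standard_normal((8, 3))
    return PrimaryModality(X=X, feature_names=["a", "b", "c"])


@pytest.fixture
def exhaustive_pairs():
    def _make(N):
        return sample_pairs(N, N * (N - 1) // 2, seed=0)

    return _make


def random_qp_instance(seed, n_pairs=30, k=2, n_secondary=1):
    """Small random (D, rhos, gammas) problem for oracle comparisons."""
    r = np.random.default_rng(seed)
    D = r.uniform(0.0, 2.0, size=(n_pairs, k))
    rhos = [r.uniform(0.0, 3.0, size=n_pairs) for _ in range(n_secondary)]
    gammas = [1.0] * n_secondary
    return D, rhos, gammas


def scalar_secondary(values, gamma=1.0, name="scalar"):
    return SecondaryModality(
        payload=np.asarray(values, float),
        metric_kind="absolute_diff",
        gamma=gamma,
        name=name,
    )
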