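import numpy as np
import pytest

import gammafs as g


@pytest.fixture(scope="session")
def small_benchmark():
    """Small simulated NSR/AF feature table shared across tests."""
    return g.make_benchmark_dataset(n_nsr=30, n_af=30, seed=12345)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def two_point_class(mean: float, sd: float):
    """Two 1-D points with exactly the given sample mean and sd (ddof=1)."""
    h = sd / np.sqrt(2.0)
    return np.array([[mean - h], [mean + h]])


def random_instance(rng, n_per_class=50, p=2, k=2):
    """Random full-rank k-class p-dim sample for oracle comparisons."""
    X, y = [], []
    for c in range(k):
        mu = rng.normal(0.0, 3.0, size=p)
        A = rng.normal(0.0, 1.0, size=(p, p))
        cov = A @ A.T + 0.2 * np.eye(p)
        X.append(rng.multivariate_normal(mu, cov, size=n_per_class))
        y.append(np.full(n_per_class, c))
    return np.vstack(X), np.concatenate(y)
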