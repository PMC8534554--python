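import numpy as np
import pytest

from idest import datasets


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ball3():
    """Uniform 3-ball, moderate size — shared across estimator tests."""
    return datasets.generate("hyperball", 1000, {"d": 3}, seed=0).points


@pytest.fixture(scope="session")
def disk2000():
    """Uniform 2-disk with 2000 points."""
    return datasets.generate("hyperball", 2000, {"d": 2}, seed=0).points


def brute_force_neighbors(X, k):
    """O(M^2) oracle: full pairwise distances, stable sort, ties by index."""
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)
    idx = np.argsort(D, axis=1, kind="stable")[:, :k]
    return idx, np.take_along_axis(D, idx, axis=1)
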