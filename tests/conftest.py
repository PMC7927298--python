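import numpy as np
import pytest

from csvdnet import WeightedConnectome


def make_connectome(weights, labels=None, coords=None):
    w = np.asarray(weights, dtype=float)
    if labels is None:
        labels = [f"n{i:02d}" for i in range(w.shape[0])]
    return WeightedConnectome(labels, w, coords)


def random_connectome(rng, n, p=0.5, weighted=True):
    """Random symmetric weighted graph; may be disconnected."""
    upper = rng.random((n, n))
    w = np.where(upper < p, rng.uniform(0.2, 3.0, size=(n, n)) if weighted else 1.0, 0.0)
    w = np.triu(w, k=1)
    w = w + w.T
    return make_connectome(w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    return make_connectome([[0, 1, 1], [1, 0, 1], [1, 1, 0]])


@pytest.fixture
def path_graph():
    return make_connectome([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
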