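import numpy as np
import pytest

from cogflex.semnet import WeightedNetwork


def random_weighted_network(n, rng, grid=None):
    """Dense symmetric weighted network; optional weight grid for coarse
    threshold resolution."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    if grid is not None:
        w = np.round(w * grid) / grid
        w = np.clip(w, 1.0 / grid, 1.0)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork([f"n{i}" for i in range(n)], w)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
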