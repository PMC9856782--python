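import numpy as np
import pytest

from fdnet import CovarianceNetwork, load_region_table


@pytest.fixture(scope="session")
def region_table():
    return load_region_table()


def network_from_edges(n, edges, weights=None):
    """Small test network from an explicit edge list."""
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        val = 1.0 if weights is None else weights[k]
        w[i, j] = w[j, i] = val
    return CovarianceNetwork(weights=w, threshold_fraction=1.0)


@pytest.fixture
def two_triangles():
    """Two disconnected unit-weight triangles: Q of the true split is 0.5."""
    return network_from_edges(
        6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230103)


def random_blob_volume(rng, max_side=20):
    """A random smoothed occupancy blob: dense enough to behave like an object."""
    from scipy.ndimage import gaussian_filter

    shape = rng.integers(6, max_side + 1, size=3)
    field = gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    grid = field > np.quantile(field, rng.uniform(0.2, 0.6))
    if not grid.any():
        grid[tuple(s // 2 for s in shape)] = True
    return grid
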