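import numpy as np
import pytest
import scipy.sparse as sp

from gntd.data import ExpressionTensor, SpotGrid
from gntd.graphs import ModeGraph, ProductGraph


def full_grid(n_y, n_x):
    """SpotGrid with every grid position in tissue (parity-aware coords)."""
    ys, xs = np.mgrid[0:n_y, 0:n_x]
    ys, xs = ys.ravel(), xs.ravel()
    return SpotGrid(
        barcodes=[f"s{y}_{x}" for y, x in zip(ys, xs)],
        array_row=ys,
        array_col=2 * xs + (ys % 2),
        n_y=n_y,
        n_x=n_x,
    )


def random_tensor(rng, n_g, n_y, n_x, observed=0.7):
    """Random nonnegative tensor over a full grid with partial observation."""
    grid = full_grid(n_y, n_x)
    vals = rng.uniform(0.5, 3.0, (n_g, n_y, n_x))
    vals[rng.random(vals.shape) >= observed] = 0.0
    return ExpressionTensor(vals, (vals > 0).astype(np.uint8),
                            [f"g{i}" for i in range(n_g)], grid)


def random_graph(rng, n, p=0.35):
    W = (rng.random((n, n)) < p).astype(float)
    W = np.triu(W, 1)
    W = W + W.T
    return ModeGraph(sp.csr_matrix(W))


def random_product_graph(rng, n_g, n_y, n_x):
    return ProductGraph(random_graph(rng, n_y * n_x), random_graph(rng, n_g))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
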