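"""Spatial and gene mode graphs and the Cartesian-product Laplacian regularizer.

The spot graph G_xy joins each in-tissue spot to its 6 nearest spots in the
hexagonal array geometry and its 10 most expression-similar spots in the top
principal components; the gene graph G_g comes from protein-protein
interaction edges. The regularizer is the Laplacian quadratic form of the
Cartesian product graph, whose Laplacian is the Kronecker sum
L_xy (+) L_g = L_xy (x) I + I (x) L_g. On a CP-form tensor this quadratic
form factorizes into Gram/Laplacian products of the factor matrices, so the
product Laplacian is never materialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .data import ExpressionTensor, SpotGrid


@dataclass
class ModeGraph:
    """Undirected binary graph over one tensor mode."""

    adjacency: sp.csr_matrix

    def __post_init__(self):
        W = sp.csr_matrix(self.adjacency)
        W.eliminate_zeros()
        if (W != W.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if W.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")
        if W.nnz and not np.all(W.data == 1):
            raise ValueError("adjacency must be binary")
        self.adjacency = W

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def laplacian(self) -> sp.csr_matrix:
        """L = D - W; positive semidefinite with zero row sums."""
        return sp.diags(self.degree) - self.adjacency

    def to_edge_list(self) -> np.ndarray:
        """(n_edges, 2) array of node-index pairs, i < j."""
        coo = sp.triu(self.adjacency).tocoo()
        return np.column_stack([coo.row, coo.col])


@dataclass
class ProductGraph:
    """Spatial graph over the n_x*n_y grid positions plus the gene graph.

    The implied Cartesian-product Laplacian L_xy (+) L_g is used only in
    factorized form.
    """

    spatial: ModeGraph
    gene: ModeGraph


def _pca_embed(X: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top principal components of rows of X, mean-centered, unscaled.

    Signs are fixed by making each component's largest-magnitude loading
    positive, so the embedding is deterministic.
    """
    Xc = X - X.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(Xc.shape) - 1) if min(Xc.shape) > 1 else 1
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return (U[:, :n_pcs] * s[:n_pcs]) * signs[:n_pcs]


def _knn_pairs(coords: np.ndarray, k: int) -> np.ndarray:
    """Directed kNN edges (i -> each of i's k nearest others), exhaustive.

    Ties in distance are broken by the smaller node index (stable argsort
    over (distance, index)).
    """
    n = coords.shape[0]
    if n < 2 or k < 1:
        return np.empty((0, 2), dtype=int)
    k = min(k, n - 1)
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    src = np.repeat(np.arange(n), k)
    return np.column_stack([src, order.ravel()])


def build_spatial_graph(
    grid: SpotGrid,
    expr: ExpressionTensor | None = None,
    k_spatial: int = 6,
    k_expr: int = 10,
    n_pcs: int = 15,
) -> ModeGraph:
    """Spot graph over all n_x*n_y grid positions.

    Each in-tissue spot is joined to its ``k_spatial`` nearest in-tissue
    spots in the physical hexagonal geometry and, when expression is given,
    to its ``k_expr`` most similar spots by Euclidean distance in the top
    ``n_pcs`` PCs of the spot x gene matrix. The edge union is symmetrized;
    out-of-tissue grid positions are isolated nodes.
    """
    n_nodes = grid.n_y * grid.n_x
    n = grid.n_spots
    if n < 2:
        return ModeGraph(sp.csr_matrix((n_nodes, n_nodes)))
    if n <= k_spatial:
        warnings.warn(
            f"only {n} in-tissue spots; reducing k_spatial from {k_spatial} to {n - 1}"
        )
        k_spatial = n - 1
    pairs = _knn_pairs(grid.spot_xy, k_spatial)
    if expr is not None:
        if expr.grid is not grid and expr.grid.barcodes != grid.barcodes:
            raise ValueError("expression tensor and grid describe different spots")
        pcs = _pca_embed(expr.spot_matrix().T, n_pcs)
        pairs = np.vstack([pairs, _knn_pairs(pcs, min(k_expr, n - 1))])
    nodes = grid.node_index()
    rows, cols = nodes[pairs[:, 0]], nodes[pairs[:, 1]]
    W = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    W = W + W.T  # symmetrize by union
    W.data[:] = 1.0
    return ModeGraph(W)


def build_gene_graph(edge_list, gene_ids) -> ModeGraph:
    """Gene graph from a PPI edge list of symbol pairs.

    Matching is case-insensitive; self-loops are dropped; symbols absent
    from ``gene_ids`` are ignored and genes without any edge stay isolated.
    """
    index = {str(g).upper(): i for i, g in enumerate(gene_ids)}
    n = len(gene_ids)
    rows, cols = [], []
    skipped = 0
    for a, b in edge_list:
        ia, ib = index.get(str(a).upper()), index.get(str(b).upper())
        if ia is None or ib is None:
            skipped += 1
            continue
        if ia == ib:
            continue
        rows.append(ia)
        cols.append(ib)
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    W = W + W.T
    if W.nnz:
        W.data[:] = 1.0
    if skipped:
        warnings.warn(f"{skipped} PPI edges referenced unknown gene symbols")
    return ModeGraph(W)


def diagonal_gene_graph(n_genes: int) -> ModeGraph:
    """Edgeless gene graph (zero Laplacian) used when no PPI is supplied.

    A diagonal adjacency W = I yields L = D - W = 0, identical in every
    model quantity to the edgeless graph, so the latter representation is
    used.
    """
    return ModeGraph(sp.csr_matrix((n_genes, n_genes)))


def _spatial_khatri_rao(factor_x: np.ndarray, factor_y: np.ndarray) -> np.ndarray:
    """Khatri-Rao product A_x (.) A_y, rows ordered x slow / y fast.

    Row x*n_y + y equals A_x[x] * A_y[y], matching SpotGrid.node_index.
    """
    n_x, r = factor_x.shape
    n_y = factor_y.shape[0]
    return (factor_x[:, None, :] * factor_y[None, :, :]).reshape(n_x * n_y, r)


def product_quadratic_form(factors, w, pg: ProductGraph) -> float:
    """Cartesian-product Laplacian quadratic form of a weighted CP tensor.

    Computes ``0.5 * vec(T)' (L_xy (+) L_g) vec(T)`` for
    ``T = [[w; A_g, A_y, A_x]]`` without materializing the Kronecker sum:
    the spatial term couples the Laplacian of G_xy with the Gram matrix of
    A_g, and the gene term couples L_g with the Grams of A_x and A_y, both
    Hadamard-weighted by w w'.

    Parameters
    ----------
    factors : tuple of ndarray
        ``(A_g, A_y, A_x)`` with a common column count.
    w : ndarray
        CP component weights.
    pg : ProductGraph
        Spatial graph over n_x*n_y grid positions and gene graph.
    """
    val, _ = _quadratic_form_impl(factors, np.asarray(w, float), pg, want_grads=False)
    return val


def quadratic_form_with_grads(factors, w, pg: ProductGraph):
    """Quadratic form plus gradients w.r.t. (A_g, A_y, A_x) and w."""
    return _quadratic_form_impl(factors, np.asarray(w, float), pg, want_grads=True)


def _quadratic_form_impl(factors, w, pg, want_grads):
    Ag, Ay, Ax = (np.asarray(f, float) for f in factors)
    r = Ag.shape[1]
    if Ay.shape[1] != r or Ax.shape[1] != r or w.shape != (r,):
        raise ValueError("factor column counts and w length must agree")
    if pg.gene.n_nodes != Ag.shape[0]:
        raise ValueError("gene graph dimension mismatch")
    if pg.spatial.n_nodes != Ax.shape[0] * Ay.shape[0]:
        raise ValueError("spatial graph must have n_x * n_y nodes")
    L_xy = pg.spatial.laplacian
    L_g = pg.gene.laplacian
    C = np.outer(w, w)
    B = _spatial_khatri_rao(Ax, Ay)
    LB = L_xy @ B
    S = B.T @ LB  # (A_x (.) A_y)' L_xy (A_x (.) A_y)
    Gg = Ag.T @ Ag
    Gx = Ax.T @ Ax
    Gy = Ay.T @ Ay
    LgAg = L_g @ Ag
    Hg = Ag.T @ LgAg
    spatial_term = 0.5 * float(np.sum(C * Gg * S))
    gene_term = 0.5 * float(np.sum(C * Hg * Gx * Gy))
    val = spatial_term + gene_term
    if -1e-8 < val < 0:  # PSD up to roundoff
        val = 0.0
    if not want_grads:
        return val, None
    dw = (Gg * S + Hg * Gx * Gy) @ w
    dAg = Ag @ (C * S) + LgAg @ (C * Gx * Gy)
    dB = LB @ (C * Gg) + B @ (C * Hg)
    dB3 = dB.reshape(Ax.shape[0], Ay.shape[0], r)
    dAx = np.einsum("xyr,yr->xr", dB3, Ay)
    dAy = np.einsum("xyr,xr->yr", dB3, Ax)
    return val, (dAg, dAy, dAx, dw)


def dense_product_laplacian(pg: ProductGraph) -> np.ndarray:
    """Materialized Kronecker-sum Laplacian, for small-instance checking only."""
    L_xy = pg.spatial.laplacian.toarray()
    L_g = pg.gene.laplacian.toarray()
    n_s, n_g = L_xy.shape[0], L_g.shape[0]
    return np.kron(L_xy, np.eye(n_g)) + np.kron(np.eye(n_s), L_g)
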