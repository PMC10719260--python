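"""Reading, preprocessing and tensorization of spot-level spatial expression data.

In-situ-capturing assays (Visium and relatives) report a gene x spot UMI
count matrix together with the array coordinates of every capture spot.
Because valid Visium positions alternate column parity per row, the raw
``(array_row, array_col)`` coordinates are compressed to a dense grid
``(y, x) = (array_row, array_col // 2)``; the expression profile then lives
naturally on a 3-way tensor (genes x y x x) with an observation mask over
the non-zero entries.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Input files are structurally inconsistent (shape/column mismatch)."""


class DataError(ValueError):
    """Input files are well-formed but semantically invalid."""


@dataclass
class SpotGrid:
    """Mapping between spot barcodes, array coordinates and dense grid indices.

    Parameters
    ----------
    barcodes : list of str
        One identifier per in-tissue spot.
    array_row, array_col : ndarray of int
        Visium array coordinates per spot.
    n_y, n_x : int, optional
        Grid extents; default to the smallest grid containing all spots.
    """

    barcodes: list
    array_row: np.ndarray
    array_col: np.ndarray
    n_y: int | None = None
    n_x: int | None = None
    y_index: np.ndarray = field(init=False)
    x_index: np.ndarray = field(init=False)
    in_tissue: np.ndarray = field(init=False)

    def __post_init__(self):
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        if len(self.barcodes) != len(set(self.barcodes)):
            raise DataError("duplicate spot barcodes")
        if self.array_row.shape != self.array_col.shape or len(self.barcodes) != self.array_row.size:
            raise FormatError("barcodes and coordinate arrays disagree in length")
        self.y_index = self.array_row.copy()
        # compress alternating column parity to a dense grid
        self.x_index = self.array_col // 2
        if self.y_index.size and (self.y_index.min() < 0 or self.x_index.min() < 0):
            raise DataError("negative array coordinates")
        pairs = set(zip(self.y_index.tolist(), self.x_index.tolist()))
        if len(pairs) != self.y_index.size:
            raise DataError("two spots share the same grid position")
        if self.n_y is None:
            self.n_y = int(self.y_index.max()) + 1 if self.y_index.size else 0
        if self.n_x is None:
            self.n_x = int(self.x_index.max()) + 1 if self.x_index.size else 0
        if self.y_index.size and (self.y_index.max() >= self.n_y or self.x_index.max() >= self.n_x):
            raise DataError("grid extents too small for spot coordinates")
        self.in_tissue = np.zeros((self.n_y, self.n_x), dtype=bool)
        self.in_tissue[self.y_index, self.x_index] = True

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def node_index(self, y=None, x=None) -> np.ndarray:
        """Spatial-graph node id of grid position(s) ``(y, x)``.

        Nodes are ordered with y fastest (node = x * n_y + y) so that the
        spatial Laplacian aligns with the Khatri-Rao product of the x and y
        factors in the vectorized CP form.
        """
        if y is None:
            y, x = self.y_index, self.x_index
        return np.asarray(x) * self.n_y + np.asarray(y)

    def subset(self, keep: np.ndarray) -> "SpotGrid":
        """Grid restricted to spots selected by boolean/index array ``keep``."""
        keep = np.asarray(keep)
        return SpotGrid(
            barcodes=[self.barcodes[i] for i in np.arange(self.n_spots)[keep]] if keep.dtype == bool
            else [self.barcodes[i] for i in keep],
            array_row=self.array_row[keep],
            array_col=self.array_col[keep],
            n_y=self.n_y,
            n_x=self.n_x,
        )

    @property
    def spot_xy(self) -> np.ndarray:
        """Physical coordinates per spot for hexagonal neighbour queries.

        Visium rows are vertically spaced sqrt(3)/2 of a spot pitch while
        array_col counts half-pitches, so (array_col, array_row * sqrt(3))
        places all six hexagonal neighbours equidistant.
        """
        return np.column_stack([self.array_col.astype(float),
                                self.array_row.astype(float) * np.sqrt(3.0)])


@dataclass
class RawCounts:
    """Gene x spot count (or normalized expression) matrix with identities."""

    matrix: np.ndarray  # dense float/int array, genes x spots
    gene_ids: list
    barcodes: list

    def __post_init__(self):
        self.matrix = np.asarray(
            self.matrix.toarray() if sp.issparse(self.matrix) else self.matrix
        )
        if self.matrix.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)


@dataclass
class ExpressionTensor:
    """Nonnegative 3-way expression tensor with observation mask.

    ``values[i, y, x]`` is the log-normalized expression of gene ``i`` at grid
    position ``(y, x)``; ``mask`` marks observed entries (by default the
    non-zero ones). Out-of-tissue grid positions are zero and unmasked.
    """

    values: np.ndarray
    mask: np.ndarray
    gene_ids: list
    grid: SpotGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.shape != self.mask.shape:
            raise FormatError("values and mask shapes differ")
        if self.values.ndim != 3:
            raise FormatError("expected a 3-way tensor")
        if self.values.min() < 0:
            raise DataError("negative expression values")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def density(self) -> float:
        """Fraction of non-zero entries over the full grid."""
        return float(np.count_nonzero(self.values)) / self.values.size

    def spot_matrix(self) -> np.ndarray:
        """Flatten back to the gene x spot matrix over the grid's spots."""
        return self.values[:, self.grid.y_index, self.grid.x_index]

    def to_anndata(self):
        """Export as an AnnData (spots x genes) carrying grid metadata."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.spot_matrix().T,
            obs=pd.DataFrame(
                {
                    "array_row": self.grid.array_row,
                    "array_col": self.grid.array_col,
                    "in_tissue": 1,
                },
                index=self.grid.barcodes,
            ),
            var=pd.DataFrame(index=self.gene_ids),
        )
        adata.obsm["spatial"] = np.column_stack(
            [self.grid.array_col, self.grid.array_row]
        )
        return adata


def _read_tsv(path) -> pd.DataFrame:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None)


def _read_positions(path) -> pd.DataFrame:
    """Read a tissue-positions CSV, with or without a header line."""
    with (gzip.open if str(path).endswith(".gz") else open)(path, "rt") as fh:
        first = fh.readline()
    has_header = "barcode" in first
    cols = ["barcode", "in_tissue", "array_row", "array_col"]
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 4:
        raise FormatError("positions file needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = cols
    return df


def load_counts(matrix_path, features_path, barcodes_path, positions_path):
    """Load a Matrix Market gene x spot count matrix plus its spot grid.

    Only spots flagged in-tissue in the positions file and present in the
    barcodes file are retained.

    Returns
    -------
    (RawCounts, SpotGrid)
    """
    mat = scipy.io.mmread(str(matrix_path)).tocsc()
    features = _read_tsv(features_path)
    barcodes = _read_tsv(barcodes_path)[0].tolist()
    gene_ids = features.iloc[:, 1 if features.shape[1] > 1 else 0].tolist()
    if mat.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix {mat.shape} inconsistent with {len(gene_ids)} features "
            f"x {len(barcodes)} barcodes"
        )
    pos = _read_positions(positions_path)
    pos = pos[pos["in_tissue"].astype(int) == 1]
    pos = pos.set_index("barcode")
    keep = [i for i, b in enumerate(barcodes) if b in pos.index]
    if not keep:
        raise DataError("no in-tissue barcodes shared between matrix and positions")
    kept_barcodes = [barcodes[i] for i in keep]
    grid = SpotGrid(
        barcodes=kept_barcodes,
        array_row=pos.loc[kept_barcodes, "array_row"].to_numpy(),
        array_col=pos.loc[kept_barcodes, "array_col"].to_numpy(),
    )
    counts = RawCounts(mat[:, keep].toarray(), gene_ids, kept_barcodes)
    return counts, grid


def load_h5ad(path):
    """Load spot expression from an H5AD file (spots x genes convention).

    Requires ``obs`` columns ``array_row``/``array_col`` (or an
    ``obsm['spatial']`` array of (col, row) pairs) and optionally
    ``in_tissue``.

    Returns
    -------
    (RawCounts, SpotGrid)
    """
    import anndata as ad

    adata = ad.read_h5ad(str(path))
    if "array_row" in adata.obs:
        row = adata.obs["array_row"].to_numpy()
        col = adata.obs["array_col"].to_numpy()
    elif "spatial" in adata.obsm:
        col, row = adata.obsm["spatial"][:, 0], adata.obsm["spatial"][:, 1]
    else:
        raise FormatError("H5AD lacks array coordinates")
    if "in_tissue" in adata.obs:
        keep = adata.obs["in_tissue"].to_numpy().astype(int) == 1
        adata = adata[keep]
        row, col = row[keep], col[keep]
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    grid = SpotGrid(
        barcodes=adata.obs_names.tolist(),
        array_row=np.asarray(row, dtype=int),
        array_col=np.asarray(col, dtype=int),
    )
    counts = RawCounts(X.T, adata.var_names.tolist(), adata.obs_names.tolist())
    return counts, grid


def preprocess(raw: RawCounts, grid: SpotGrid | None = None, min_spots: int = 10):
    """CPM + log1p normalization with gene and spot filtering.

    Spots with zero total count are removed; genes expressed in fewer than
    ``min_spots`` spots are removed; remaining counts ``c`` in a spot with
    total ``s`` become ``log(1 + 1e6 * c / s)``.

    Returns ``(RawCounts, SpotGrid)`` when a grid is given (so the spot
    subset stays aligned), otherwise just the ``RawCounts``.
    """
    m = np.asarray(raw.matrix, dtype=float)
    if np.any(m < 0):
        raise DataError("negative counts")
    spot_totals = m.sum(axis=0)
    spot_keep = spot_totals > 0
    m = m[:, spot_keep]
    gene_keep = (m > 0).sum(axis=1) >= min_spots
    if not gene_keep.any():
        raise DataError("all genes removed by the expression filter")
    m = m[gene_keep]
    cpm = m * (1e6 / m.sum(axis=0, keepdims=True))
    out = RawCounts(
        np.log1p(cpm),
        [g for g, k in zip(raw.gene_ids, gene_keep) if k],
        [b for b, k in zip(raw.barcodes, spot_keep) if k],
    )
    if grid is not None:
        return out, (grid if spot_keep.all() else grid.subset(spot_keep))
    return out


def tensorize(raw: RawCounts, grid: SpotGrid) -> ExpressionTensor:
    """Scatter a gene x spot matrix onto the (genes, n_y, n_x) grid tensor.

    The observation mask follows the non-zero convention: an entry is
    observed iff its value is positive.
    """
    if raw.n_spots != grid.n_spots or raw.barcodes != grid.barcodes:
        raise DataError("counts and grid describe different spot sets")
    values = np.zeros((raw.n_genes, grid.n_y, grid.n_x))
    values[:, grid.y_index, grid.x_index] = raw.matrix
    mask = (values > 0).astype(np.uint8)
    return ExpressionTensor(values, mask, list(raw.gene_ids), grid)
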