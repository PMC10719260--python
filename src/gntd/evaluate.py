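"""Cross-validation protocols, imputation metrics, clustering and pattern AUC.

Imputation accuracy is evaluated on the observed (non-zero) entries only,
since zeros in capture-based data mix true biological zeros with dropouts.
Spot-wise CV assigns whole spots to folds; gene-wise CV stratifies each
gene's observed entries across folds. Fold predictions are combined before
metric computation, and metrics are reported as means of per-spot or
per-gene scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .data import ExpressionTensor
from .graphs import ProductGraph, _pca_embed
from .model import GNTD, GntdConfig


@dataclass
class FoldAssignment:
    """Partition of observed tensor entries into k CV folds.

    ``entries`` holds flat indices into the tensor; ``fold_of_entry`` the
    1-based fold of each.
    """

    mode: str  # "spot_wise" | "gene_wise"
    entries: np.ndarray
    fold_of_entry: np.ndarray
    k: int
    seed: int

    def test_entries(self, fold: int) -> np.ndarray:
        return self.entries[self.fold_of_entry == fold]


@dataclass
class EvalReport:
    """Imputation metrics with per-unit breakdown (and optional labels)."""

    rmse: float
    mae: float
    mape: float
    r2: float
    per_unit: pd.DataFrame
    ari: float | None = None
    per_gene_auc: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {"rmse": self.rmse, "mae": self.mae, "mape": self.mape, "r2": self.r2}
        if self.ari is not None:
            d["ari"] = self.ari
        if self.per_gene_auc is not None:
            d["min_auc"] = float(np.min(self.per_gene_auc))
            d["mean_auc"] = float(np.mean(self.per_gene_auc))
        return d


def split_folds(tensor: ExpressionTensor, mode: str, k: int = 10,
                seed: int = 0) -> FoldAssignment:
    """Assign observed (masked) entries to k folds.

    spot_wise: spots are randomly split into k folds and every observed
    entry inherits its spot's fold. gene_wise: each gene's observed entries
    are spread across folds with per-fold counts differing by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in ("spot_wise", "gene_wise"):
        raise ValueError("mode must be 'spot_wise' or 'gene_wise'")
    rng = np.random.default_rng(seed)
    mask = tensor.mask.astype(bool)
    n_g, n_y, n_x = tensor.shape
    grid = tensor.grid
    if mode == "spot_wise":
        n_spots = grid.n_spots
        if n_spots < k:
            raise ValueError("fewer spots than folds")
        spot_fold = 1 + (rng.permutation(n_spots) % k)
        entries_list, folds_list = [], []
        for s in range(n_spots):
            y, x = grid.y_index[s], grid.x_index[s]
            genes = np.flatnonzero(mask[:, y, x])
            flat = genes * (n_y * n_x) + y * n_x + x
            entries_list.append(flat)
            folds_list.append(np.full(flat.size, spot_fold[s]))
        entries = np.concatenate(entries_list)
        folds = np.concatenate(folds_list)
    else:
        entries_list, folds_list = [], []
        short_genes = 0
        for gi in range(n_g):
            flat = np.flatnonzero(mask[gi].ravel()) + gi * (n_y * n_x)
            if flat.size == 0:
                continue
            if flat.size < k:
                short_genes += 1
            perm = rng.permutation(flat.size)
            # stratified deal: shuffled fold order, round-robin
            fold_order = 1 + rng.permutation(k)
            folds = fold_order[np.arange(flat.size) % k]
            entries_list.append(flat[perm])
            folds_list.append(folds)
        if short_genes:
            warnings.warn(f"{short_genes} genes have fewer than {k} observed "
                          "entries; their entries span fewer folds")
        entries = np.concatenate(entries_list)
        folds = np.concatenate(folds_list)
    return FoldAssignment(mode, entries, folds, k, seed)


def imputation_metrics(truth, predicted):
    """(RMSE, MAE, MAPE, R2) of predictions against non-zero truth values.

    R2 is 1 - SS_res/SS_tot and may be negative; for constant truth it is
    undefined and reported as NaN.
    """
    t = np.asarray(truth, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if t.size != p.size:
        raise ValueError("truth and prediction lengths differ")
    if t.size == 0:
        raise ValueError("empty metric vectors")
    err = t - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err / t)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(err**2)) / ss_tot
    return rmse, mae, mape, r2


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement of two partitions (contingency-table form).

    Invariant to label permutation; identical partitions score 1 (including
    the degenerate single-cluster case).
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def spatial_pattern_auc(values, labels) -> float:
    """Mann-Whitney AUC of high-labeled spots over low-labeled spots.

    Ties receive average ranks, so all-equal values score 0.5.
    """
    v = np.asarray(values, float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if v.size != y.size:
        raise ValueError("values and labels differ in length")
    n_hi = int(y.sum())
    n_lo = y.size - n_hi
    if n_hi == 0 or n_lo == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(v)
    u = ranks[y].sum() - n_hi * (n_hi + 1) / 2.0
    return float(u / (n_hi * n_lo))


def _spot_matrix_pcs(tensor, n_pcs, gene_set, hvg_top):
    X = tensor.spot_matrix().T  # spots x genes
    if gene_set == "hvg" and X.shape[1] > hvg_top:
        mean = X.mean(axis=0)
        var = X.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            dispersion = np.where(mean > 0, var / mean, 0.0)
        keep = np.argsort(-dispersion, kind="stable")[:hvg_top]
        X = X[:, np.sort(keep)]
    return _pca_embed(X, n_pcs)


def cluster_spots(tensor: ExpressionTensor, n_clusters: int, n_pcs: int = 15,
                  gene_set: str = "all", hvg_top: int = 2000,
                  seed: int = 0) -> np.ndarray:
    """Gaussian-mixture clustering of in-tissue spots on expression PCs.

    Full covariance, k-means initialization, 10 restarts with the best
    likelihood kept; deterministic given the seed.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n_spots = tensor.grid.n_spots
    if n_spots < n_clusters:
        raise ValueError("fewer spots than clusters")
    if n_clusters == 1:
        return np.zeros(n_spots, dtype=int)
    pcs = _spot_matrix_pcs(tensor, n_pcs, gene_set, hvg_top)
    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        n_init=10,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-4,
    )
    return gmm.fit_predict(pcs)


def cluster_genes(tensor: ExpressionTensor, k: int = 100, n_pcs: int = 50,
                  seed: int = 0) -> np.ndarray:
    """k-means co-expression clustering of genes on gene x spot PCs."""
    n_g = tensor.n_genes
    if n_g < k:
        raise ValueError("fewer genes than clusters")
    X = tensor.spot_matrix()  # genes x spots
    pcs = _pca_embed(X, min(n_pcs, min(X.shape) - 1))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(pcs)


def run_cross_validation(tensor: ExpressionTensor, graphs: ProductGraph | None,
                         config: GntdConfig, folds: FoldAssignment,
                         predict_fn=None, verbose: bool = False) -> EvalReport:
    """k-fold CV: hide each test fold, fit, predict, then score combined.

    ``predict_fn(tensor, train_mask) -> full imputed tensor`` may replace
    the default GNTD fit (used for protocol checks with stub predictors).
    Metrics are computed per spot (vectors over that spot's test entries)
    or per gene, then averaged; units without test entries are excluded.
    """
    n_g, n_y, n_x = tensor.shape
    pred_flat = np.full(tensor.values.size, np.nan)
    for fold in range(1, folds.k + 1):
        test = folds.test_entries(fold)
        if test.size == 0:
            continue
        train_mask = tensor.mask.copy().astype(np.uint8)
        train_mask.ravel()[test] = 0
        if predict_fn is not None:
            imputed = predict_fn(tensor, train_mask)
        else:
            res = GNTD(tensor, graphs, config=config, mask=train_mask).fit()
            imputed = res.tensor_hat
        pred_flat[test] = imputed.ravel()[test]
        if verbose:
            print(f"fold {fold}/{folds.k}: {test.size} test entries")
    evaluated = folds.entries
    truth = tensor.values.ravel()[evaluated]
    pred = pred_flat[evaluated]
    # per-unit breakdown
    if folds.mode == "spot_wise":
        unit = (evaluated % (n_y * n_x))  # flat grid position
        unit_name = "spot"
    else:
        unit = evaluated // (n_y * n_x)
        unit_name = "gene"
    rows = []
    for u in np.unique(unit):
        sel = unit == u
        if not sel.any():
            continue
        rmse, mae, mape, r2 = imputation_metrics(truth[sel], pred[sel])
        rows.append((u, sel.sum(), rmse, mae, mape, r2))
    per_unit = pd.DataFrame(
        rows, columns=[unit_name, "n_entries", "rmse", "mae", "mape", "r2"]
    )
    means = per_unit[["rmse", "mae", "mape", "r2"]].mean(skipna=True)
    return EvalReport(
        rmse=float(means["rmse"]),
        mae=float(means["mae"]),
        mape=float(means["mape"]),
        r2=float(means["r2"]),
        per_unit=per_unit,
    )
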