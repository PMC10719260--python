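"""Graph-guided neural tensor decomposition (GNTD).

The model is a three-layer neural parameterization of a canonical polyadic
(CP) decomposition of the expression tensor T (genes x y x x):

1. an embedding layer producing linear factors ``A_m = E_m W_m_emb`` per
   mode m in {g, y, x} (``E_m`` is the identity one-hot embedding);
2. a nonlinear mapping layer ``At_m = PReLU(A_m W_m_nlin; a_m)`` with a
   learnable slope ``a_m`` in [0, 1];
3. a nonlinear aggregation layer combining the nonlinear factors in a
   weighted CP sum ``Tt = sum_i w_i At_g[:,i] o At_y[:,i] o At_x[:,i]`` with
   an output ReLU, ``Th = max(Tt, 0)``.

Training minimizes the masked reconstruction loss
``0.5 * ||M * (T - Th)||_F^2`` plus ``lambda`` times the Cartesian-product
graph Laplacian quadratic form evaluated on the pre-activation CP form Tt.
Optimization is full-batch Adam with validation-based early stopping; all
gradients are analytic (verified against finite differences in the tests).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionTensor
from .graphs import ProductGraph, diagonal_gene_graph, quadratic_form_with_grads

MODES = ("g", "y", "x")


@dataclass
class GntdConfig:
    """Hyperparameters of the GNTD model and its training protocol.

    Parameters
    ----------
    rank : int
        CP rank ``n_r`` of the embedding layer (paper-tuned grid
        {8, 16, 32, 64, 128}).
    nonlinear_rank : int, optional
        Column count of the nonlinear factors; defaults to ``rank``.
    lam : float
        Weight on the product-graph Laplacian regularizer (0 disables it).
    learning_rate : float
        Initial Adam learning rate; decayed by ``lr_decay`` whenever the
        validation MSE fails to improve for ``lr_patience`` epochs (down to
        ``min_learning_rate``). The decay-on-plateau schedule keeps the
        aggressive initial rate from oscillating the reconstruction through
        the output ReLU's dead zone.
    warmup_epochs, patience : int
        Early stopping waits ``warmup_epochs`` before counting ``patience``
        epochs without validation improvement.
    val_fraction : float
        Fraction of observed entries held out for validation monitoring.
    loss_on : {"nonzero", "all"}
        Whether the reconstruction loss runs over observed (non-zero)
        entries only, or over every tensor entry.
    """

    rank: int = 64
    nonlinear_rank: int | None = None
    lam: float = 0.1
    learning_rate: float = 0.05
    max_epochs: int = 2000
    warmup_epochs: int = 1000
    patience: int = 50
    val_fraction: float = 0.10
    seed: int = 0
    loss_on: str = "nonzero"
    lr_decay: float = 0.5
    lr_patience: int = 25
    min_learning_rate: float = 1e-3

    def __post_init__(self):
        if self.nonlinear_rank is None:
            self.nonlinear_rank = self.rank
        if self.rank < 1 or self.nonlinear_rank < 1:
            raise ValueError("ranks must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.loss_on not in ("nonzero", "all"):
            raise ValueError("loss_on must be 'nonzero' or 'all'")


@dataclass
class GntdParams:
    """Learnable parameters: per-mode embedding/nonlinear weights, PReLU
    slopes, and CP aggregation weights."""

    W_emb: dict  # mode -> (n_m, n_r)
    W_nlin: dict  # mode -> (n_r, nt_r)
    a: dict  # mode -> scalar in [0, 1]
    w: np.ndarray  # (nt_r,)

    def copy(self) -> "GntdParams":
        return GntdParams(
            {m: v.copy() for m, v in self.W_emb.items()},
            {m: v.copy() for m, v in self.W_nlin.items()},
            dict(self.a),
            self.w.copy(),
        )

    def flat(self):
        """(name, array) pairs in a fixed order, for the optimizer."""
        for m in MODES:
            yield f"W_emb_{m}", self.W_emb[m]
            yield f"W_nlin_{m}", self.W_nlin[m]
        for m in MODES:
            yield f"a_{m}", np.asarray(self.a[m], dtype=float)
        yield "w", self.w


def embed(params: GntdParams, mode: str) -> np.ndarray:
    """Linear factor A_m of one mode; with the identity one-hot embedding
    this is the embedding weight matrix itself."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    return params.W_emb[mode]


def nonlinear_map(A: np.ndarray, W_nlin: np.ndarray, a: float) -> np.ndarray:
    """Nonlinear factor: parametric ReLU of A @ W_nlin with slope a."""
    Z = A @ W_nlin
    return np.maximum(Z, 0.0) + a * np.minimum(Z, 0.0)


def aggregate(At_g, At_y, At_x, w):
    """Weighted CP aggregation of the nonlinear factors.

    Returns ``(Th, Tt)``: the imputed tensor after the output ReLU and the
    pre-activation CP form (the regularizer operates on the latter).
    """
    At_g, At_y, At_x = (np.asarray(f, float) for f in (At_g, At_y, At_x))
    w = np.asarray(w, float)
    r = At_g.shape[1]
    if At_y.shape[1] != r or At_x.shape[1] != r or w.shape != (r,):
        raise ValueError("factor column counts and w length must agree")
    K = At_y[:, None, :] * (At_x * w)[None, :, :]  # (n_y, n_x, r)
    Tt = np.tensordot(At_g, K, axes=([1], [2]))
    return np.maximum(Tt, 0.0), Tt


def reconstruction_loss(T, Th, M) -> float:
    """Masked squared reconstruction error 0.5 * ||M * (T - Th)||_F^2."""
    d = np.asarray(M, float) * (np.asarray(T, float) - np.asarray(Th, float))
    return 0.5 * float(np.sum(d * d))


def _forward(params: GntdParams):
    A = {m: embed(params, m) for m in MODES}
    Z = {m: A[m] @ params.W_nlin[m] for m in MODES}
    At = {
        m: np.maximum(Z[m], 0.0) + params.a[m] * np.minimum(Z[m], 0.0) for m in MODES
    }
    Th, Tt = aggregate(At["g"], At["y"], At["x"], params.w)
    return A, Z, At, Th, Tt


def total_loss(params: GntdParams, tensor: ExpressionTensor, pg: ProductGraph,
               lam: float, mask: np.ndarray | None = None) -> float:
    """Reconstruction loss plus lam times the product-graph quadratic form
    on the pre-activation CP factors."""
    _, _, At, Th, _ = _forward(params)
    loss = reconstruction_loss(tensor.values, Th, tensor.mask if mask is None else mask)
    if lam > 0:
        val, _ = quadratic_form_with_grads((At["g"], At["y"], At["x"]), params.w, pg)
        loss += lam * val
    return loss


def _loss_and_grads(params, T, M_train, pg, lam):
    """Analytic gradient of the total loss w.r.t. every parameter."""
    A, Z, At, Th, Tt = _forward(params)
    R = M_train * (Th - T)
    recon = 0.5 * float(np.sum(R * R))
    dTt = R * (Tt > 0)
    Atw_x = At["x"] * params.w
    # CP chain: dAt_m[g,i] = sum over the other two modes of dTt * their factors
    dAt = {}
    K = At["y"][:, None, :] * Atw_x[None, :, :]
    dAt["g"] = np.tensordot(dTt, K, axes=([1, 2], [0, 1]))
    P = np.tensordot(dTt, At["g"], axes=([0], [0]))  # (n_y, n_x, r)
    dAt["y"] = np.einsum("yxr,xr->yr", P, Atw_x)
    dAxw = np.einsum("yxr,yr->xr", P, At["y"])
    dAt["x"] = dAxw * params.w
    dw = np.einsum("xr,xr->r", dAxw, At["x"])
    reg = 0.0
    if lam > 0:
        reg, (gAg, gAy, gAx, gw) = quadratic_form_with_grads(
            (At["g"], At["y"], At["x"]), params.w, pg
        )
        dAt["g"] = dAt["g"] + lam * gAg
        dAt["y"] = dAt["y"] + lam * gAy
        dAt["x"] = dAt["x"] + lam * gAx
        dw = dw + lam * gw
    grads = {"w": dw}
    for m in MODES:
        dZ = dAt[m] * np.where(Z[m] > 0, 1.0, params.a[m])
        grads[f"a_{m}"] = np.asarray(np.sum(dAt[m] * np.minimum(Z[m], 0.0)))
        grads[f"W_nlin_{m}"] = A[m].T @ dZ
        grads[f"W_emb_{m}"] = dZ @ params.W_nlin[m].T
    return recon + lam * reg, recon, grads


class _Adam:
    """Minimal Adam optimizer over a dict of arrays/scalars."""

    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v = {}, {}
        self.t = 0

    def step(self, values: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, g in grads.items():
            m = self.m.get(k, np.zeros_like(g))
            v = self.v.get(k, np.zeros_like(g))
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.m[k], self.v[k] = m, v
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            out[k] = values[k] - self.lr * mh / (np.sqrt(vh) + self.eps)
        return out


class GNTD:
    """GNTD model bound to an expression tensor and mode graphs.

    Parameters
    ----------
    tensor : ExpressionTensor
        Log-normalized expression tensor with its observation mask.
    graphs : ProductGraph, optional
        Spatial and gene graphs; when omitted (or when ``lam`` is 0) the
        regularizer vanishes and an edgeless gene graph is assumed.
    config : GntdConfig, optional
        Hyperparameters; keyword overrides (e.g. ``rank=32``) are applied
        on top.
    mask : ndarray, optional
        Training mask overriding the tensor's own (used by the
        cross-validation driver to hide test entries).

    Examples
    --------
    >>> model = GNTD(tensor, graphs, rank=32, lam=0.1, seed=0)
    >>> res = model.fit()
    >>> imputed = res.impute()
    """

    def __init__(self, tensor: ExpressionTensor, graphs: ProductGraph | None = None,
                 config: GntdConfig | None = None, mask: np.ndarray | None = None,
                 **overrides):
        self.tensor = tensor
        self.config = replace(config, **overrides) if config else GntdConfig(**overrides)
        if graphs is None:
            from .graphs import ModeGraph
            import scipy.sparse as sp

            n_s = tensor.grid.n_y * tensor.grid.n_x
            graphs = ProductGraph(
                ModeGraph(sp.csr_matrix((n_s, n_s))),
                diagonal_gene_graph(tensor.n_genes),
            )
        self.graphs = graphs
        base_mask = tensor.mask if mask is None else np.asarray(mask)
        if self.config.loss_on == "all":
            base_mask = np.ones_like(tensor.values, dtype=np.uint8)
        self.mask = base_mask.astype(float)
        if self.mask.sum() < 1:
            raise ValueError("tensor has no observed entries to train on")
        n_g, n_y, n_x = tensor.shape
        if graphs.gene.n_nodes != n_g:
            raise ValueError("gene graph does not match tensor gene count")
        if graphs.spatial.n_nodes != n_y * n_x:
            raise ValueError("spatial graph does not match grid size")

    @classmethod
    def from_anndata(cls, adata, graphs=None, min_spots: int = 10, **overrides):
        """Build from an AnnData (spots x genes with array coordinates),
        running the standard CPM/log1p preprocessing and tensorization."""
        import tempfile
        from pathlib import Path

        from .data import load_h5ad, preprocess, tensorize

        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "input.h5ad"
            adata.write_h5ad(path)
            raw, grid = load_h5ad(path)
        norm, grid = preprocess(raw, grid, min_spots=min_spots)
        return cls(tensorize(norm, grid), graphs, **overrides)

    def _init_params(self, rng) -> GntdParams:
        """Mixed-sign uniform initialization in [-1/sqrt(rank), 1/sqrt(rank)].

        The symmetric fan-in-scaled range (the standard fully-connected
        layer initialization) keeps the trilinear forward model balanced
        around zero; an all-positive start at the data magnitude makes the
        first full-batch adaptive steps overshoot through the output ReLU's
        dead zone and stall. PReLU slopes start at the conventional 0.25
        and the aggregation weights at 1.
        """
        n_g, n_y, n_x = self.tensor.shape
        n_m = {"g": n_g, "y": n_y, "x": n_x}
        r, rt = self.config.rank, self.config.nonlinear_rank
        scale = 1.0 / np.sqrt(r)
        return GntdParams(
            W_emb={m: rng.uniform(-scale, scale, size=(n_m[m], r)) for m in MODES},
            W_nlin={m: rng.uniform(-scale, scale, size=(r, rt)) for m in MODES},
            a={m: 0.25 for m in MODES},
            w=np.ones(rt),
        )

    def _split_validation(self, rng):
        """Hold out val_fraction of the training-mask entries for monitoring."""
        obs = np.flatnonzero(self.mask.ravel())
        n_val = max(1, int(round(self.config.val_fraction * obs.size)))
        if n_val >= obs.size:
            n_val = obs.size - 1
        val_idx = rng.choice(obs, size=n_val, replace=False)
        val_mask = np.zeros(self.mask.size)
        val_mask[val_idx] = 1.0
        val_mask = val_mask.reshape(self.mask.shape)
        return self.mask * (1 - val_mask), val_mask

    def fit(self, start_params: GntdParams | None = None,
            validation_mask: np.ndarray | None = None,
            callback=None) -> "GNTDResults":
        """Train by full-batch Adam with validation early stopping.

        The observed entries are split 90/10 into train/validation by the
        config seed; validation MSE is monitored and, once past the warmup
        epochs, training stops after ``patience`` epochs without
        improvement. The best-validation parameter snapshot is returned.

        Parameters
        ----------
        start_params : GntdParams, optional
            Initial parameters overriding the seeded random initialization.
        validation_mask : ndarray, optional
            Explicit validation entries overriding the seeded 90/10 split
            (must be a subset of the training mask).
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = start_params.copy() if start_params is not None else self._init_params(rng)
        if validation_mask is not None:
            M_val = np.asarray(validation_mask, float)
            M_train = self.mask * (1 - M_val)
        else:
            M_train, M_val = self._split_validation(rng)
        n_val = M_val.sum()
        T = self.tensor.values
        opt = _Adam(cfg.learning_rate)
        log = []
        best = (np.inf, None, -1)  # val MSE, params, epoch
        stall = 0
        t0 = time.perf_counter()
        for epoch in range(1, cfg.max_epochs + 1):
            loss, recon, grads = _loss_and_grads(
                params, T, M_train, self.graphs, cfg.lam
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} "
                    f"(recon={recon!r}, lam={cfg.lam}); try a smaller learning rate"
                )
            values = dict(params.flat())
            updated = opt.step(values, grads)
            for m in MODES:
                params.W_emb[m] = updated[f"W_emb_{m}"]
                params.W_nlin[m] = updated[f"W_nlin_{m}"]
                # PReLU slope constrained by clamping after each step
                params.a[m] = float(np.clip(updated[f"a_{m}"], 0.0, 1.0))
            params.w = updated["w"]
            _, _, _, Th, _ = _forward(params)
            val_mse = float(np.sum(M_val * (T - Th) ** 2) / n_val)
            log.append((epoch, loss, val_mse))
            if callback:
                callback(epoch, loss, val_mse)
            if val_mse < best[0]:
                best = (val_mse, params.copy(), epoch)
                stall = 0
            else:
                stall += 1
                if stall % cfg.lr_patience == 0 and opt.lr > cfg.min_learning_rate:
                    opt.lr = max(opt.lr * cfg.lr_decay, cfg.min_learning_rate)
            if epoch > cfg.warmup_epochs and stall >= cfg.patience:
                break
        runtime = time.perf_counter() - t0
        history = pd.DataFrame(log, columns=["epoch", "train_loss", "val_mse"])
        return GNTDResults(self, best[1], history, best[2], best[0], runtime)


@dataclass
class GNTDResults:
    """Fitted GNTD model: best-validation parameters, log and queries."""

    model: GNTD
    params: GntdParams
    history: pd.DataFrame
    best_epoch: int
    best_val_mse: float
    runtime_s: float
    _tensor_hat: np.ndarray | None = field(default=None, repr=False)

    @property
    def config(self) -> GntdConfig:
        return self.model.config

    def factors(self) -> dict:
        """Linear and nonlinear factor matrices per mode, plus weights w."""
        A = {m: embed(self.params, m) for m in MODES}
        At = {
            m: nonlinear_map(A[m], self.params.W_nlin[m], self.params.a[m])
            for m in MODES
        }
        return {"linear": A, "nonlinear": At, "w": self.params.w.copy()}

    @property
    def tensor_hat(self) -> np.ndarray:
        """Imputed tensor (post output-ReLU), cached."""
        if self._tensor_hat is None:
            f = self.factors()
            Th, _ = aggregate(
                f["nonlinear"]["g"], f["nonlinear"]["y"], f["nonlinear"]["x"], f["w"]
            )
            self._tensor_hat = Th
        return self._tensor_hat

    def impute(self, indices=None) -> np.ndarray:
        """Imputed values at (i, j, k) triples, or the full tensor.

        All returned values are nonnegative; out-of-range or negative
        indices raise IndexError.
        """
        Th = self.tensor_hat
        if indices is None:
            return Th.copy()
        idx = np.asarray(indices)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("indices must be an (n, 3) array of triples")
        if idx.min() < 0 or np.any(idx >= np.array(Th.shape)):
            raise IndexError("tensor index out of range")
        return Th[idx[:, 0], idx[:, 1], idx[:, 2]]

    def imputed_tensor(self) -> ExpressionTensor:
        """Imputed expression wrapped as an ExpressionTensor (full mask on
        in-tissue positions)."""
        t = self.model.tensor
        mask = np.zeros_like(t.values, dtype=np.uint8)
        mask[:, t.grid.y_index, t.grid.x_index] = 1
        vals = self.tensor_hat * mask
        return ExpressionTensor(vals, (vals > 0).astype(np.uint8), list(t.gene_ids), t.grid)

    def summary(self) -> str:
        cfg = self.config
        n_g, n_y, n_x = self.model.tensor.shape
        lines = [
            "GNTD Results",
            "=" * 46,
            f"tensor shape         {n_g} genes x {n_y} x {n_x}",
            f"observed entries     {int(self.model.mask.sum())}"
            f" ({self.model.mask.mean():.1%} of grid)",
            f"rank / nonlin. rank  {cfg.rank} / {cfg.nonlinear_rank}",
            f"lambda               {cfg.lam}",
            f"epochs run           {len(self.history)}",
            f"best epoch           {self.best_epoch}",
            f"best validation MSE  {self.best_val_mse:.6f}",
            f"final train loss     {self.history['train_loss'].iloc[-1]:.4f}",
            f"runtime              {self.runtime_s:.1f} s",
        ]
        return "\n".join(lines)

    def save(self, path):
        """Checkpoint parameters and config as a single .npz archive."""
        arrays = {name: np.asarray(arr) for name, arr in self.params.flat()}
        arrays.update({f"a_{m}": np.array(self.params.a[m]) for m in MODES})
        cfg = self.config
        arrays["config"] = np.array(
            [cfg.rank, cfg.nonlinear_rank, cfg.lam, cfg.learning_rate, cfg.seed]
        )
        np.savez(path, **arrays)

    def plot_training(self, ax=None):
        """Training-loss / validation-MSE curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train loss")
        ax2 = ax.twinx()
        ax2.plot(self.history["epoch"], self.history["val_mse"], color="C1",
                 label="val MSE")
        ax.set_xlabel("epoch")
        ax.set_ylabel("train loss")
        ax2.set_ylabel("validation MSE")
        return ax
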