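"""Forward model, losses, gradients, training and imputation queries."""

import numpy as np
import pytest

from gntd.data import ExpressionTensor
from gntd.graphs import ProductGraph, diagonal_gene_graph
from gntd.model import (GNTD, GntdConfig, GntdParams, MODES, _forward,
                        _loss_and_grads, aggregate, embed, nonlinear_map,
                        reconstruction_loss, total_loss)

from conftest import random_product_graph, random_tensor


def make_params(rng, n_g, n_y, n_x, r, rt=None, spread=1.0):
    rt = rt or r
    n_m = {"g": n_g, "y": n_y, "x": n_x}
    return GntdParams(
        W_emb={m: rng.uniform(-spread, spread, (n_m[m], r)) for m in MODES},
        W_nlin={m: rng.uniform(-spread, spread, (r, rt)) for m in MODES},
        a={m: 0.25 + 0.1 * i for i, m in enumerate(MODES)},
        w=rng.uniform(0.5, 1.5, rt),
    )


class TestForwardLayers:
    def test_embed_identity_and_direct(self, rng):
        p = make_params(rng, 4, 3, 3, 2)
        p.W_emb["g"] = np.eye(4)
        np.testing.assert_array_equal(embed(p, "g"), np.eye(4))
        np.testing.assert_array_equal(embed(p, "y"), p.W_emb["y"])
        with pytest.raises(ValueError):
            embed(p, "z")

    def test_nonlinear_map_slope_one_is_linear(self, rng):
        A = rng.normal(size=(4, 3))
        W = rng.normal(size=(3, 3))
        np.testing.assert_allclose(nonlinear_map(A, W, 1.0), A @ W)

    def test_nonlinear_map_slope_zero_relu(self):
        A = np.array([[1.0]])
        W = np.array([[-2.0, 3.0]])
        np.testing.assert_array_equal(nonlinear_map(A, W, 0.0), [[0.0, 3.0]])

    def test_nonlinear_map_half_slope(self):
        out = nonlinear_map(np.eye(1), np.array([[2.0, -2.0]]), 0.5)
        np.testing.assert_array_equal(out, [[2.0, -1.0]])

    def test_aggregate_all_ones_rank_one(self):
        Th, Tt = aggregate(np.ones((2, 1)), np.ones((3, 1)), np.ones((4, 1)),
                           np.array([1.0]))
        np.testing.assert_array_equal(Th, np.ones((2, 3, 4)))
        np.testing.assert_array_equal(Tt, np.ones((2, 3, 4)))

    def test_aggregate_zero_weights(self, rng):
        Th, _ = aggregate(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)),
                          rng.normal(size=(2, 3)), np.zeros(3))
        np.testing.assert_array_equal(Th, np.zeros((2, 2, 2)))

    def test_aggregate_matches_loop_oracle(self, rng):
        Ag, Ay, Ax = (rng.normal(size=(3, 3)), rng.normal(size=(2, 3)),
                      rng.normal(size=(2, 3)))
        w = rng.normal(size=3)
        Th, Tt = aggregate(Ag, Ay, Ax, w)
        for g in range(3):
            for y in range(2):
                for x in range(2):
                    ref = sum(w[i] * Ag[g, i] * Ay[y, i] * Ax[x, i]
                              for i in range(3))
                    assert Tt[g, y, x] == pytest.approx(ref, abs=1e-10)
                    assert Th[g, y, x] == pytest.approx(max(ref, 0), abs=1e-10)

    def test_aggregate_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            aggregate(rng.normal(size=(2, 2)), rng.normal(size=(2, 3)),
                      rng.normal(size=(2, 3)), np.ones(3))


class TestLosses:
    def test_reconstruction_loss_cases(self, rng):
        T = rng.uniform(0, 2, (2, 2, 2))
        assert reconstruction_loss(T, T, np.ones_like(T)) == 0.0
        assert reconstruction_loss(T, np.zeros_like(T), np.zeros_like(T)) == 0.0
        assert reconstruction_loss(np.array([2.0]), np.array([0.0]),
                                   np.array([1.0])) == 2.0

    def test_total_loss_lambda_zero_is_reconstruction(self, rng):
        t = random_tensor(rng, 3, 2, 2)
        pg = random_product_graph(rng, 3, 2, 2)
        p = make_params(rng, 3, 2, 2, 2)
        _, _, _, Th, _ = _forward(p)
        assert total_loss(p, t, pg, 0.0) == pytest.approx(
            reconstruction_loss(t.values, Th, t.mask))

    def test_total_loss_edgeless_graphs(self, rng):
        t = random_tensor(rng, 3, 2, 2)
        pg = ProductGraph(diagonal_gene_graph(4), diagonal_gene_graph(3))
        p = make_params(rng, 3, 2, 2, 2)
        assert total_loss(p, t, pg, 5.0) == total_loss(p, t, pg, 0.0)

    def test_total_loss_is_sum_of_components(self, rng):
        from gntd.graphs import product_quadratic_form

        t = random_tensor(rng, 3, 2, 3)
        pg = random_product_graph(rng, 3, 2, 3)
        p = make_params(rng, 3, 2, 3, 2)
        _, _, At, Th, _ = _forward(p)
        lam = 0.7
        expected = (reconstruction_loss(t.values, Th, t.mask)
                    + lam * product_quadratic_form(
                        (At["g"], At["y"], At["x"]), p.w, pg))
        assert total_loss(p, t, pg, lam) == pytest.approx(expected, rel=1e-12)


def test_gradients_match_finite_differences(rng):
    """Analytic gradients of the full loss vs central differences."""
    n_g, n_y, n_x, r = 4, 3, 5, 3
    t = random_tensor(rng, n_g, n_y, n_x, observed=0.6)
    pg = random_product_graph(rng, n_g, n_y, n_x)
    p = make_params(rng, n_g, n_y, n_x, r)
    lam = 0.37
    M = t.mask.astype(float)
    _, _, grads = _loss_and_grads(p, t.values, M, pg, lam)

    def loss_of(params):
        l, _, _ = _loss_and_grads(params, t.values, M, pg, lam)
        return l

    eps = 1e-6
    for name, arr in p.flat():
        g = np.asarray(grads[name])
        for idx in (np.ndindex(arr.shape) if arr.ndim else [()]):
            q = p.copy()
            if name.startswith("a_"):
                m = name[-1]
                q.a[m] = p.a[m] + eps
                up = loss_of(q)
                q.a[m] = p.a[m] - eps
                dn = loss_of(q)
                num, ana = (up - dn) / (2 * eps), float(g)
            else:
                if name == "w":
                    target = q.w
                else:
                    kind, m = name.rsplit("_", 1)
                    target = q.W_emb[m] if kind == "W_emb" else q.W_nlin[m]
                orig = target[idx]
                target[idx] = orig + eps
                up = loss_of(q)
                target[idx] = orig - eps
                dn = loss_of(q)
                num, ana = (up - dn) / (2 * eps), g[idx]
            assert ana == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestFit:
    def test_recovers_noiseless_low_rank_tensor(self, rng):
        # planted nonnegative rank-2 CP tensor, half observed, no graphs
        n_g, n_y, n_x = 6, 5, 5
        A = rng.uniform(0.2, 1, (n_g, 2))
        B = rng.uniform(0.2, 1, (n_y, 2))
        C = rng.uniform(0.2, 1, (n_x, 2))
        T = np.einsum("gr,yr,xr->gyx", A, B, C)
        obs = rng.random(T.shape) < 0.5
        t = random_tensor(rng, n_g, n_y, n_x)
        t.values = T * obs
        t.mask = obs.astype(np.uint8)
        res = GNTD(t, None, rank=6, lam=0.0, seed=0, max_epochs=1500,
                   warmup_epochs=600).fit()
        held = ~obs
        r2 = 1 - (np.sum((T[held] - res.tensor_hat[held]) ** 2)
                  / np.sum((T[held] - T[held].mean()) ** 2))
        assert r2 > 0.9

    def test_regularizer_vanishes_identical_trajectories(self, rng):
        # lam=0 with real graphs vs lam=0.1 with edgeless graphs: exact match
        t = random_tensor(rng, 4, 3, 3)
        pg_edgeless = ProductGraph(diagonal_gene_graph(9), diagonal_gene_graph(4))
        pg_diag = ProductGraph(diagonal_gene_graph(9), diagonal_gene_graph(4))
        r1 = GNTD(t, pg_diag, rank=3, lam=0.0, seed=7, max_epochs=60,
                  warmup_epochs=60).fit()
        r2 = GNTD(t, pg_edgeless, rank=3, lam=0.1, seed=7, max_epochs=60,
                  warmup_epochs=60).fit()
        np.testing.assert_array_equal(r1.history["train_loss"].values,
                                      r2.history["train_loss"].values)

    def test_best_val_not_worse_than_first_epoch(self, rng):
        t = random_tensor(rng, 5, 4, 4)
        res = GNTD(t, None, rank=3, lam=0.0, seed=2, max_epochs=120,
                   warmup_epochs=120).fit()
        assert res.best_val_mse <= res.history["val_mse"].iloc[0]

    def test_degenerate_cpd_equivalence(self, rng):
        # identity nonlinearity + identity mixing + unit weights = plain CPD
        n_g, n_y, n_x, r = 4, 3, 2, 3
        p = make_params(rng, n_g, n_y, n_x, r)
        for m in MODES:
            p.W_emb[m] = rng.uniform(0, 1, p.W_emb[m].shape)  # nonnegative
            p.W_nlin[m] = np.eye(r)
            p.a[m] = 1.0
        p.w = np.ones(r)
        _, _, _, Th, Tt = _forward(p)
        cpd = np.einsum("gr,yr,xr->gyx", p.W_emb["g"], p.W_emb["y"],
                        p.W_emb["x"])
        # equal up to floating-point reassociation of the rank sum
        np.testing.assert_allclose(Th, cpd, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(Tt, cpd, rtol=1e-12, atol=1e-15)

    def test_gene_permutation_equivariance(self, rng):
        n_g, n_y, n_x, r = 5, 3, 3, 2
        t = random_tensor(rng, n_g, n_y, n_x)
        pg = random_product_graph(rng, n_g, n_y, n_x)
        perm = rng.permutation(n_g)
        t_p = ExpressionTensor(t.values[perm], t.mask[perm],
                               [t.gene_ids[i] for i in perm], t.grid)
        Wg = pg.gene.adjacency.toarray()[np.ix_(perm, perm)]
        import scipy.sparse as sp

        from gntd.graphs import ModeGraph

        pg_p = ProductGraph(pg.spatial, ModeGraph(sp.csr_matrix(Wg)))
        cfg = dict(rank=r, lam=0.05, seed=0, max_epochs=40, warmup_epochs=40)
        m1 = GNTD(t, pg, **cfg)
        m2 = GNTD(t_p, pg_p, **cfg)
        start = m1._init_params(np.random.default_rng(0))
        start_p = start.copy()
        start_p.W_emb["g"] = start.W_emb["g"][perm]
        val = np.zeros_like(t.values)
        flat = np.flatnonzero(t.mask)[:: 7]
        val.ravel()[flat] = 1
        val = val * t.mask
        r1 = m1.fit(start_params=start, validation_mask=val)
        r2 = m2.fit(start_params=start_p, validation_mask=val[perm])
        np.testing.assert_allclose(r2.tensor_hat, r1.tensor_hat[perm],
                                   rtol=1e-8, atol=1e-10)

    def test_lambda_pressure_monotone(self, rng):
        # stronger regularization never increases the quadratic form at the end
        from gntd.graphs import product_quadratic_form

        t = random_tensor(rng, 5, 4, 4, observed=0.8)
        pg = random_product_graph(rng, 5, 4, 4)
        qfs = []
        for lam in [0.0, 0.01, 0.1, 1.0]:
            res = GNTD(t, pg, rank=3, lam=lam, seed=4, max_epochs=400,
                       warmup_epochs=400).fit()
            f = res.factors()
            qfs.append(product_quadratic_form(
                (f["nonlinear"]["g"], f["nonlinear"]["y"], f["nonlinear"]["x"]),
                f["w"], pg))
        assert all(b <= a * (1 + 1e-6) + 1e-9 for a, b in zip(qfs, qfs[1:]))

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_nonfinite_loss_aborts(self, rng):
        t = random_tensor(rng, 2, 2, 2)
        t.values[t.mask.astype(bool)] = 1e200
        with pytest.raises(FloatingPointError):
            GNTD(t, None, rank=2, lam=0.0, seed=0, max_epochs=10,
                 warmup_epochs=10).fit()

    def test_prelu_slopes_stay_in_unit_interval(self, rng):
        t = random_tensor(rng, 4, 3, 3)
        res = GNTD(t, None, rank=2, lam=0.0, seed=1, max_epochs=80,
                   warmup_epochs=80).fit()
        for m in MODES:
            assert 0.0 <= res.params.a[m] <= 1.0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    t = random_tensor(rng, 4, 3, 3)
    return GNTD(t, None, rank=2, lam=0.0, seed=5, max_epochs=50,
                warmup_epochs=50).fit()


class TestResults:

    def test_impute_full_matches_aggregate(self, fitted):
        f = fitted.factors()
        Th, _ = aggregate(f["nonlinear"]["g"], f["nonlinear"]["y"],
                          f["nonlinear"]["x"], f["w"])
        np.testing.assert_array_equal(fitted.impute(), Th)
        assert fitted.impute().min() >= 0.0

    def test_impute_subset_consistency(self, fitted, rng):
        full = fitted.impute()
        idx = np.column_stack([rng.integers(0, s, 10) for s in full.shape])
        np.testing.assert_array_equal(fitted.impute(idx),
                                      full[idx[:, 0], idx[:, 1], idx[:, 2]])

    def test_impute_invalid_indices(self, fitted):
        with pytest.raises(IndexError):
            fitted.impute(np.array([[-1, 0, 0]]))
        with pytest.raises(IndexError):
            fitted.impute(np.array([[0, 99, 0]]))

    def test_summary_and_checkpoint(self, fitted, tmp_path):
        s = fitted.summary()
        assert "rank" in s and "validation MSE" in s
        fitted.save(tmp_path / "ckpt.npz")
        arrays = np.load(tmp_path / "ckpt.npz")
        assert arrays["W_emb_g"].shape == (4, 2)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"rank": 0}, {"lam": -0.1}, {"val_fraction": 1.5},
        {"loss_on": "some"},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GntdConfig(**kwargs)

    def test_nonlinear_rank_defaults_to_rank(self):
        assert GntdConfig(rank=16).nonlinear_rank == 16

    def test_loss_on_all_uses_every_entry(self, rng):
        t = random_tensor(rng, 3, 2, 2, observed=0.5)
        m = GNTD(t, None, rank=2, loss_on="all")
        assert m.mask.sum() == t.values.size
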