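"""Penalized-path solver against independent oracles, and model selection.

Oracles are deliberately naive: the soft-threshold closed form for one
feature, normal equations for the lambda->0 limit, and a plain proximal
(ISTA) minimizer of the objective for the general case.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import blocklasso as bl
from blocklasso.lassocore import lasso_objective, _standardize_train


def _ista(X, y, lam, n_iter=200_000):
    """Brute-force proximal-gradient minimizer of (1/2N)||y-Xb||^2 + lam|b|."""
    n, m = X.shape
    L = np.linalg.norm(X, 2) ** 2 / n  # Lipschitz constant of the gradient
    step = 1.0 / L
    b = np.zeros(m)
    for _ in range(n_iter):
        grad = X.T @ (X @ b - y) / n
        z = b - step * grad
        b_new = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0)
        if np.max(np.abs(b_new - b)) < 1e-12:
            return b_new
        b = b_new
    return b


def _std(X, y):
    Xs, *_ = _standardize_train(X)
    return Xs, y - y.mean()


class TestLambdaGrid:
    def test_grid_endpoints(self, rng):
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        grid = bl.make_lambda_grid(X, y, n_points=2, ratio=0.1)
        assert len(grid) == 2
        assert grid.lambdas[1] == pytest.approx(0.1 * grid.lambdas[0])

    def test_lambda_max_direct_computation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        x = (x - x.mean()) / x.std()
        y = 0.5 * x  # x'y/N = 0.5 for standardized x
        grid = bl.make_lambda_grid(x[:, None], y, n_points=3, ratio=0.01)
        assert grid.lambdas[0] == pytest.approx(0.5, rel=1e-10)

    def test_zero_solution_at_lambda_max(self, rng):
        """KKT: beta = 0 exactly at and above lambda_max."""
        X = rng.standard_normal((60, 8))
        y = X[:, 0] + rng.standard_normal(60)
        grid = bl.make_lambda_grid(X, y, n_points=50, ratio=1e-3)
        path = bl.fit_lasso_path(X, y, grid)
        assert path.n_nonzero[0] == 0
        assert path.n_nonzero[-1] > 0

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            bl.make_lambda_grid(rng.standard_normal((20, 3)), np.ones(20))

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            bl.LambdaGrid(np.array([1.0, 2.0]))  # increasing
        with pytest.raises(ValueError):
            bl.LambdaGrid(np.array([1.0, 0.0]))  # non-positive


class TestSolverOracles:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.9), st.integers(0, 2**31 - 1))
    def test_single_feature_soft_threshold(self, lam, seed):
        """beta(lam) = sign(c) max(|c|-lam, 0) for one standardized feature."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(100)
        y = rng.uniform(-1, 1) * x + 0.3 * rng.standard_normal(100)
        grid = bl.LambdaGrid(np.array([max(lam, 0.02), max(lam, 0.02) / 2]))
        path = bl.fit_lasso_path(x[:, None], y, grid)
        xs, yc = _std(x[:, None], y)
        c = float(xs[:, 0] @ yc) / 100
        for i, l in enumerate(grid.lambdas):
            expect = np.sign(c) * max(abs(c) - l, 0.0)
            assert path.coefs[0, i] == pytest.approx(expect, abs=1e-6)

    def test_small_lambda_approaches_ols(self, rng):
        X = rng.standard_normal((50, 5))
        y = X @ rng.uniform(-1, 1, 5) + 0.1 * rng.standard_normal(50)
        grid = bl.LambdaGrid(np.array([1e-6]))
        path = bl.fit_lasso_path(X, y, grid, tol=1e-10)
        Xs, yc = _std(X, y)
        ols = np.linalg.solve(Xs.T @ Xs, Xs.T @ yc)
        assert np.allclose(path.coefs[:, 0], ols, atol=1e-4)

    def test_matches_proximal_gradient_minimizer(self):
        """Random 20x10 problems: coordinates agree with ISTA to 1e-4."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((20, 10))
            y = X[:, :3] @ np.array([1.0, -0.5, 0.25]) + 0.2 * rng.standard_normal(20)
            Xs, yc = _std(X, y)
            lam = 0.5 * np.max(np.abs(Xs.T @ yc)) / 20
            path = bl.fit_lasso_path(X, y, bl.LambdaGrid(np.array([lam])), tol=1e-12)
            ref = _ista(Xs, yc, lam)
            assert np.max(np.abs(path.coefs[:, 0] - ref)) <= 1e-4

    def test_objective_no_worse_than_zero_vector(self, rng):
        X = rng.standard_normal((40, 15))
        y = X[:, 0] + rng.standard_normal(40)
        grid = bl.make_lambda_grid(X, y, 20, 1e-2)
        path = bl.fit_lasso_path(X, y, grid)
        Xs, yc = _std(X, y)
        for i, lam in enumerate(grid.lambdas):
            at_sol = lasso_objective(Xs, yc, path.coefs[:, i], lam)
            at_zero = lasso_objective(Xs, yc, np.zeros(Xs.shape[1]), lam)
            assert at_sol <= at_zero + 1e-12

    def test_sparsity_weakly_increases_down_the_path(self, rng):
        X = rng.standard_normal((80, 20))
        y = X[:, :4] @ np.ones(4) + rng.standard_normal(80)
        path = bl.fit_lasso_path(X, y, bl.make_lambda_grid(X, y, 40, 1e-3))
        nnz = path.n_nonzero
        # small transient drops are numerically possible; forbid big ones
        assert np.all(np.diff(nnz.astype(int)) >= -2)
        assert nnz[-1] >= nnz[0]

    def test_non_finite_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            bl.fit_lasso_path(X, y, bl.LambdaGrid(np.array([0.1])))

    def test_standardization_round_trip(self, rng):
        """Original-scale weights reproduce standardized-scale predictions."""
        X = rng.integers(0, 3, size=(100, 10)).astype(float)
        y = X[:, 1] - X[:, 5] + rng.standard_normal(100)
        grid = bl.make_lambda_grid(X, y, 20, 1e-2)
        path = bl.fit_lasso_path(X[:60], y[:60], grid)
        meta = pd.DataFrame({"snv_id": [f"s{j}" for j in range(10)],
                             "chrom": 1, "pos_bp": np.arange(10), "a1": "G"})
        model = bl.select_model(path, X[60:80], y[60:80], "correlation", "b1", meta)
        cols = [int(s[1:]) for s in model.features["snv_id"]]
        raw = X[80:][:, cols] @ model.beta_raw
        std = ((X[80:][:, cols] - model.mean) / model.sd) @ model.beta_std
        offset = (model.mean / model.sd) @ model.beta_std
        assert np.allclose(raw, std + offset, atol=1e-10)


class TestSelectModel:
    def _path_and_meta(self, rng, n=120, m=8):
        X = rng.integers(0, 3, size=(n, m)).astype(float)
        y = X[:, 0] + 0.5 * rng.standard_normal(n)
        grid = bl.make_lambda_grid(X[: n // 2], y[: n // 2], 30, 1e-3)
        path = bl.fit_lasso_path(X[: n // 2], y[: n // 2], grid)
        meta = pd.DataFrame({"snv_id": [f"s{j}" for j in range(m)],
                             "chrom": 1, "pos_bp": np.arange(m), "a1": "G"})
        return X, y, path, meta

    def test_argmax_of_validation_metric(self, rng):
        X, y, path, meta = self._path_and_meta(rng)
        val = slice(60, 120)
        model = bl.select_model(path, X[val], y[val], "correlation", "b", meta)
        scores = path.predict(X[val])
        cors = [
            np.corrcoef(scores[:, i], y[val])[0, 1] if scores[:, i].std() > 0 else -np.inf
            for i in range(scores.shape[1])
        ]
        assert model.lambda_sel == pytest.approx(path.lambdas[int(np.argmax(cors))])

    def test_tie_goes_to_larger_lambda(self):
        # constant columns of predictions -> engineered tie via a path
        # with two identical coefficient vectors
        path = bl.LassoPathResult(
            lambdas=np.array([0.5, 0.1]),
            coefs=np.array([[1.0, 1.0]]),
            intercept=0.0,
            feature_idx=np.array([0]),
            mean=np.array([0.0]),
            sd=np.array([1.0]),
        )
        X_val = np.arange(10, dtype=float)[:, None]
        y_val = np.arange(10, dtype=float)
        model = bl.select_model(path, X_val, y_val)
        assert model.lambda_sel == 0.5

    def test_all_zero_path_returns_flagged_null(self, rng):
        path = bl.LassoPathResult(
            lambdas=np.array([1.0, 0.5]),
            coefs=np.zeros((3, 2)),
            intercept=0.0,
            feature_idx=np.arange(3),
            mean=np.zeros(3),
            sd=np.ones(3),
        )
        model = bl.select_model(path, rng.standard_normal((20, 3)), rng.standard_normal(20))
        assert model.is_null
        assert model.n_nonzero == 0


class TestFitBlocks:
    def test_single_block_equals_plain_fit(self, small_sim):
        _, g, y, _ = small_sim
        train, val = np.arange(0, 200), np.arange(200, 300)
        block = g.blocks[0]
        sel = np.arange(block.n_snvs)
        models = bl.fit_blocks(g, {block.block_id: sel}, y, train, val)
        assert len(models) == len(g.blocks)
        grid = bl.make_lambda_grid(block.dosages[train], y[train])
        path = bl.fit_lasso_path(block.dosages[train], y[train], grid)
        meta = block.snvs[["snv_id", "chrom", "pos_bp", "a1"]]
        direct = bl.select_model(path, block.dosages[val], y[val],
                                 "correlation", block.block_id, meta)
        fitted = models[0]
        assert fitted.lambda_sel == pytest.approx(direct.lambda_sel)
        assert np.allclose(fitted.beta_std, direct.beta_std)
        # blocks with no selected features are null
        assert all(m.is_null for m in models[1:])

    def test_block_order_independence(self, small_sim):
        _, g, y, _ = small_sim
        train, val = np.arange(0, 200), np.arange(200, 300)
        sel = {b.block_id: np.arange(b.n_snvs) for b in g.blocks}
        models_fwd = bl.fit_blocks(g, sel, y, train, val)
        g_rev = bl.GenotypeBlockSet(blocks=list(reversed(g.blocks)),
                                    sample_ids=g.sample_ids)
        models_rev = bl.fit_blocks(g_rev, sel, y, train, val)
        by_id_fwd = {m.block_id: m for m in models_fwd}
        for m in models_rev:
            assert np.allclose(m.beta_std, by_id_fwd[m.block_id].beta_std)

    def test_causal_free_blocks_select_near_null_models(self):
        cfg = bl.SimConfig(n_samples=600, n_blocks=4, n_features_per_block=40,
                           seed=33)
        g = bl.simulate_genotype_blocks(cfg)
        rng = np.random.default_rng(34)
        beta = rng.uniform(0.5, 1.0, 10)
        y = g.blocks[0].dosages[:, :10] @ beta  # all signal in block 1
        y = y + 0.3 * y.std() * rng.standard_normal(600)
        sel = {b.block_id: np.arange(b.n_snvs) for b in g.blocks}
        models = bl.fit_blocks(g, sel, y, np.arange(400), np.arange(400, 500))
        assert models[0].n_nonzero >= 5
        # near-null in the predictive sense: causal-free blocks carry no
        # held-out signal, whatever their (noise-fit) support size
        held = np.arange(500, 600)
        sm = bl.block_scores(g, models, held)
        cors = [
            abs(np.corrcoef(sm.scores[:, b], y[held])[0, 1]) if sm.scores[:, b].std() > 0 else 0.0
            for b in range(4)
        ]
        assert cors[0] > 0.7
        assert max(cors[1:]) < 0.3
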