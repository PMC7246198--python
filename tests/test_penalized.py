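import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phytoland.data_model import DesignMatrix, z_transform
from phytoland.families import invlogit
from phytoland.penalized import (
    bootstrap_interval,
    bootstrap_ridge,
    build_interaction_design,
    cv_select_lambda,
    fit_penalized,
    interaction_lasso,
)

SM_FAMILIES = {
    "gaussian": sm.families.Gaussian(),
    "binomial": sm.families.Binomial(),
    "poisson": sm.families.Poisson(),
}


def _design(X, y, family, groups=None, unscaled=None):
    cols = [f"x{j}" for j in range(X.shape[1])]
    return DesignMatrix(
        X=pd.DataFrame(X, columns=cols),
        y=y,
        family=family,
        groups=np.arange(len(y)) if groups is None else groups,
        unscaled=tuple(cols) if unscaled is None else unscaled,
    )


def _grouped_binomial(seed, n_plants=45, k=10, p=10, effect=1.0):
    """Plant-level predictors expanded to caterpillars, binomial response."""
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_plants), k)
    Xp = z_transform(rng.standard_normal((n_plants, p)))
    X = z_transform(Xp[groups])
    eta = 0.34 + effect * X[:, 0]
    y = (rng.random(n_plants * k) < invlogit(eta)).astype(float)
    return _design(X, y, "binomial", groups=groups, unscaled=()), rng


class TestSolverOracles:
    def test_lasso_equals_soft_threshold_on_orthonormal_design(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((40, 4))
        M -= M.mean(axis=0)
        Q = np.linalg.qr(M)[0]  # orthonormal, mean-zero columns
        y = Q @ np.array([1.5, 0.0, -0.8, 0.3])
        fit = fit_penalized(_design(Q, y, "gaussian"), "lasso", lambda_grid=[0.5])
        ols = Q.T @ y
        expected = np.sign(ols) * np.maximum(np.abs(ols) - 0.5, 0.0)
        assert np.max(np.abs(fit.coefs[0] - expected)) < 1e-6
        assert fit.coefs[0][0] == pytest.approx(1.0, abs=1e-6)

    def test_ridge_single_predictor_closed_form(self):
        # sum(xy) = 10, sum(x^2) = 5, lambda = 5 -> beta = 10 / (5 + 5) = 1
        x = np.array([1.0, 2.0])
        y = np.array([2.0, 4.0])
        fit = fit_penalized(
            _design(x[:, None], y, "gaussian"), "ridge", lambda_grid=[5.0], fit_intercept=False
        )
        assert fit.coefs[0][0] == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "poisson"])
    def test_lambda_zero_matches_independent_irls_oracle(self, family):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(20):
            n, p = 60, 4
            X = z_transform(rng.standard_normal((n, p)))
            eta = 0.3 + X @ np.array([0.5, -0.4, 0.2, 0.0])
            if family == "gaussian":
                y = eta + rng.standard_normal(n)
            elif family == "binomial":
                y = (rng.random(n) < invlogit(eta)).astype(float)
                if len(np.unique(y)) < 2:
                    continue
            else:
                y = rng.poisson(np.exp(eta)).astype(float)
            fit = fit_penalized(_design(X, y, family, unscaled=()), "lasso", lambda_grid=[0.0])
            oracle = sm.GLM(y, sm.add_constant(X), family=SM_FAMILIES[family]).fit()
            worst = max(
                worst,
                abs(fit.intercepts[0] - oracle.params[0]),
                float(np.max(np.abs(fit.coefs[0] - oracle.params[1:]))),
            )
        assert worst < 1e-5

    def test_all_coefficients_zero_at_top_of_auto_grid(self):
        rng = np.random.default_rng(1)
        X = z_transform(rng.standard_normal((50, 6)))
        y = X @ np.array([1.0, 0, 0, 0, 0, 0]) + rng.standard_normal(50)
        fit = fit_penalized(_design(X, y, "gaussian", unscaled=()), "lasso", n_lambda=20)
        assert np.all(fit.coefs[0] == 0.0)

    def test_ridge_norm_non_increasing_in_lambda(self):
        rng = np.random.default_rng(2)
        X = z_transform(rng.standard_normal((50, 5)))
        y = X @ np.array([1.0, -0.5, 0.3, 0, 0]) + rng.standard_normal(50)
        fit = fit_penalized(_design(X, y, "gaussian", unscaled=()), "ridge", n_lambda=30)
        norms = np.linalg.norm(fit.coefs, axis=1)
        # grid is descending in lambda, so norms ascend
        assert np.all(np.diff(norms) >= -1e-10)


class TestCrossValidation:
    def test_pure_noise_rarely_selects_predictors(self):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            groups = np.repeat(np.arange(30), 6)
            Xp = z_transform(rng.standard_normal((30, 8)))
            X = z_transform(Xp[groups])
            y = (rng.random(180) < 0.55).astype(float)
            d = _design(X, y, "binomial", groups=groups, unscaled=())
            fit = cv_select_lambda(d, "lasso", n_lambda=30)
            hits += int(len(fit.nonzero()) <= 1)
        assert hits >= 0.8 * n_seeds

    def test_strong_predictor_reliably_selected(self):
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            d, _ = _grouped_binomial(2000 + s, effect=1.0)
            fit = cv_select_lambda(d, "lasso", n_lambda=30)
            hits += int("x0" in fit.nonzero())
        assert hits >= 0.95 * n_seeds

    def test_cv_curve_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = z_transform(rng.standard_normal((20, 3)))
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        groups = np.repeat([0, 1], 10)
        d = _design(X, y, "gaussian", groups=groups, unscaled=())
        a = cv_select_lambda(d, "lasso", n_lambda=15)
        b = cv_select_lambda(d, "lasso", n_lambda=15)
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)
        assert a.chosen_lambda == b.chosen_lambda

    def test_single_fold_rejected(self):
        rng = np.random.default_rng(4)
        X = z_transform(rng.standard_normal((10, 2)))
        d = _design(X, X[:, 0], "gaussian", groups=np.zeros(10), unscaled=())
        with pytest.raises(ValueError, match="folds"):
            cv_select_lambda(d, "lasso")


class TestBootstrap:
    def test_hand_fixed_replicates_interval_spans_zero(self):
        lo, hi, flag = bootstrap_interval([-1.0, -0.5, 0.5, 1.0])
        assert lo < 0 < hi and not flag

    def test_unanimous_positive_replicates_flagged(self):
        lo, hi, flag = bootstrap_interval([0.2, 0.5, 0.9, 1.3])
        assert flag and lo > 0

    def test_strong_effect_flagged_with_cluster_bootstrap(self):
        hits = 0
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(3000 + s)
            n_plants, k, p = 45, 10, 15
            groups = np.repeat(np.arange(n_plants), k)
            Xp = z_transform(rng.standard_normal((n_plants, p)))
            X = z_transform(Xp[groups])
            y = 10 + 1.0 * X[:, 0] + 2.0 * rng.standard_normal(n_plants * k)
            d = _design(X, y, "gaussian", groups=groups, unscaled=())
            out = bootstrap_ridge(d, B=200, lam=1.0, seed=s)
            hits += int(out.set_index("term").loc["x0", "excludes_zero"])
        assert hits >= 0.9 * n_seeds

    def test_degenerate_binomial_resamples_redrawn_and_counted(self):
        rng = np.random.default_rng(5)
        n = 40
        X = z_transform(rng.standard_normal((n, 2)))
        y = np.r_[np.ones(n - 1), 0.0]  # a single failure: many degenerate resamples
        d = _design(X, y, "binomial", groups=np.arange(n), unscaled=())
        out = bootstrap_ridge(d, B=20, lam=5.0, unit="row", seed=0)
        assert out.attrs["n_redraws"] > 0


class TestInteractions:
    def test_design_dimensions(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            rng.standard_normal((30, 10)), columns=[f"c{j}" for j in range(10)]
        )
        out = build_interaction_design(df)
        assert out.shape[1] == 10 + 45
        assert "c0:c1" in out.columns and "c0:c0" not in out.columns

    def test_large_p_column_count(self):
        # p main effects + p(p-1)/2 products
        p = 163
        assert p + p * (p - 1) // 2 == 13366

    def test_noiseless_product_signal_identified(self):
        rng = np.random.default_rng(7)
        n = 200
        df = pd.DataFrame(
            rng.standard_normal((n, 2)), columns=["a", "b"]
        )
        X = build_interaction_design(df)
        y = 2.0 * X["a:b"].to_numpy()
        d = DesignMatrix(
            X=X, y=y, family="gaussian", groups=np.arange(n), unscaled=()
        )
        fit = fit_penalized(d, "lasso", lambda_grid=[1e-6])
        beta = pd.Series(fit.coefs[0], index=X.columns)
        assert beta.abs().idxmax() == "a:b"
        assert beta["a:b"] == pytest.approx(2.0, abs=1e-3)

    def test_planted_interaction_recovered(self):
        hits = 0
        n_seeds = 6
        for s in range(n_seeds):
            rng = np.random.default_rng(4000 + s)
            n_plants, k, p = 45, 10, 20
            groups = np.repeat(np.arange(n_plants), k)
            base = pd.DataFrame(
                rng.standard_normal((n_plants, p)), columns=[f"c{j}" for j in range(p)]
            )
            Xp = build_interaction_design(base)
            X = z_transform(Xp.to_numpy()[groups])
            y = (
                10
                + 1.5 * X[:, list(Xp.columns).index("c0:c1")]
                + 1.0 * rng.standard_normal(n_plants * k)
            )
            d = DesignMatrix(
                X=pd.DataFrame(X, columns=Xp.columns),
                y=y,
                family="gaussian",
                groups=groups,
                unscaled=(),
            )
            out = interaction_lasso(d, n_lambda=15)
            hits += int("c0:c1" in set(out["term"]))
        assert hits >= 0.8 * n_seeds

    def test_null_data_yields_sparse_interactions(self):
        fracs = []
        for s in range(5):
            rng = np.random.default_rng(5000 + s)
            n_plants, k, p = 30, 6, 10
            groups = np.repeat(np.arange(n_plants), k)
            base = pd.DataFrame(
                rng.standard_normal((n_plants, p)), columns=[f"c{j}" for j in range(p)]
            )
            Xp = build_interaction_design(base)
            X = z_transform(Xp.to_numpy()[groups])
            y = rng.standard_normal(n_plants * k)
            d = DesignMatrix(
                X=pd.DataFrame(X, columns=Xp.columns),
                y=y,
                family="gaussian",
                groups=groups,
                unscaled=(),
            )
            out = interaction_lasso(d, n_lambda=25)
            n_inter = p * (p - 1) // 2
            fracs.append(len(out) / n_inter)
        assert np.mean(fracs) < 0.05
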