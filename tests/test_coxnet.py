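"""Elastic-net Cox path fitting against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest

from ironsig import (
    CoxnetConfig,
    cross_validate,
    fit_path,
    relative_risk,
    select_features,
    simulate_cohort,
)
from ironsig.coxnet import lambda_max, panel_matrix
from ironsig.io import GenePanel, compute_zscores
from conftest import planted_config


def toy_cohort(seed=0, n=40, p=2, censor=0.2):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.linspace(0.7, -0.5, p)
    t = rng.exponential(1.0 / (0.05 * np.exp(X @ beta)))
    e = rng.random(n) >= censor
    if e.sum() < 3:
        e[:3] = True
    cols = [f"g{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), t, e


def breslow_neg_loglik(X, t, e, beta):
    """Independent brute-force Breslow negative mean partial log-likelihood."""
    eta = X @ beta
    ll = 0.0
    for tau in np.unique(t[e]):
        d = ((t == tau) & e).sum()
        ll += eta[(t == tau) & e].sum() - d * np.log(np.exp(eta[t >= tau]).sum())
    return -ll / len(t)


class TestPathStructure:
    def test_all_zero_at_lambda_max(self):
        X, t, e = toy_cohort(1)
        path = fit_path(X, t, e, CoxnetConfig())
        assert np.all(path.coefficients[0] == 0.0)
        assert path.lambdas[0] == pytest.approx(lambda_max(X, t, e, 0.95))

    def test_lambdas_strictly_decreasing_and_density_grows(self):
        X, t, e = toy_cohort(2, n=60, p=5)
        path = fit_path(X, t, e, CoxnetConfig())
        assert (np.diff(path.lambdas) < 0).all()
        nnz = (path.coefficients != 0).sum(axis=1)
        assert nnz[0] == 0
        assert nnz[-1] >= nnz[0]

    def test_objective_descends_within_each_lambda(self):
        X, t, e = toy_cohort(3, n=80, p=6)
        path = fit_path(X, t, e, CoxnetConfig())
        for trace in path.sweep_objectives:
            if len(trace) > 1:
                assert (np.diff(trace) <= 1e-9).all()

    def test_fit_invariant_to_sample_and_gene_order(self):
        X, t, e = toy_cohort(4, n=50, p=3)
        path = fit_path(X, t, e, CoxnetConfig())
        perm = np.random.default_rng(0).permutation(len(t))
        path_s = fit_path(X.iloc[perm], t[perm], e[perm], CoxnetConfig())
        assert np.allclose(path.coefficients, path_s.coefficients, atol=1e-6)
        cols = list(X.columns)[::-1]
        path_g = fit_path(X[cols], t, e, CoxnetConfig())
        assert np.allclose(
            path.coefficients_at(path.lambdas[-1]).reindex(cols).to_numpy(),
            path_g.coefficients[-1],
            atol=1e-6,
        )

    def test_zero_events_rejected(self):
        X, t, _ = toy_cohort(5)
        with pytest.raises(ValueError):
            fit_path(X, t, np.zeros(len(t), bool), CoxnetConfig())


class TestOracleAgreement:
    def test_near_zero_lambda_matches_partial_likelihood_mle(self):
        lifelines = pytest.importorskip("lifelines")
        X, t, e = toy_cohort(6)
        cfg = CoxnetConfig(alpha=1.0, n_lambda=60, lambda_min_ratio=1e-6, tol=1e-9)
        path = fit_path(X, t, e, cfg)
        df = X.copy()
        df["T"], df["E"] = t, e
        mle = lifelines.CoxPHFitter().fit(df, "T", "E").params_.reindex(X.columns)
        assert np.abs(path.coefficients[-1] - mle.to_numpy()).max() < 1e-4

    def test_single_binary_covariate_grid_search(self):
        # lambda -> 0 solution vs direct minimization of the Breslow
        # negative partial log-likelihood over a fine beta grid.
        rng = np.random.default_rng(7)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.9 * x)))
        t += rng.uniform(0, 1e-6, n)  # break ties so Breslow == exact
        e = np.ones(n, bool)
        X = pd.DataFrame({"g": x})
        cfg = CoxnetConfig(alpha=1.0, n_lambda=60, lambda_min_ratio=1e-6, tol=1e-9)
        path = fit_path(X, t, e, cfg)
        grid = np.linspace(-3, 3, 20001)
        losses = [breslow_neg_loglik(X.to_numpy(), t, e, np.array([b])) for b in grid]
        beta_star = grid[int(np.argmin(losses))]
        assert path.coefficients[-1][0] == pytest.approx(beta_star, abs=1e-3)

    def test_lasso_single_covariate_matches_penalized_grid(self):
        # With alpha = 1 and one covariate, the fit at moderate lambda must
        # match direct grid minimization of the penalized objective.
        rng = np.random.default_rng(8)
        n = 80
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.6 * x)))
        e = np.ones(n, bool)
        X = pd.DataFrame({"g": x})
        cfg = CoxnetConfig(alpha=1.0, n_lambda=30, lambda_min_ratio=0.05, tol=1e-10)
        path = fit_path(X, t, e, cfg)
        for idx in (5, 15, 29):
            lam = path.lambdas[idx]
            grid = np.linspace(-2, 2, 40001)
            losses = [
                breslow_neg_loglik(X.to_numpy(), t, e, np.array([b]))
                + lam * abs(b)
                for b in grid
            ]
            beta_star = grid[int(np.argmin(losses))]
            assert path.coefficients[idx][0] == pytest.approx(beta_star, abs=2e-3)


class TestCrossValidation:
    def test_same_seed_same_selection(self):
        cfg = planted_config(seed=21, n_samples=150, n_genes=15)
        expr, clinical, _ = simulate_cohort(cfg)
        z = compute_zscores(expr)
        X, t, e = panel_matrix(z, GenePanel("all", tuple(expr.index)), clinical)
        cv1 = cross_validate(X, t, e, CoxnetConfig(seed=5))
        cv2 = cross_validate(X, t, e, CoxnetConfig(seed=5))
        assert cv1.lambda_min == cv2.lambda_min
        assert cv1.selected_genes == cv2.selected_genes
        assert np.allclose(cv1.mean_deviance, cv2.mean_deviance)

    def test_planted_genes_dominate_selection(self):
        cfg = planted_config(seed=22, n_samples=300)
        expr, clinical, _ = simulate_cohort(cfg)
        z = compute_zscores(expr)
        X, t, e = panel_matrix(z, GenePanel("all", tuple(expr.index)), clinical)
        cv = cross_validate(X, t, e, CoxnetConfig(seed=0))
        top3 = cv.selected_genes[:3]
        assert set(top3) == {"G1", "G2", "G3"}
        coef = cv.selection.coefficients
        assert coef["G1"] > 0 and coef["G2"] > 0 and coef["G3"] < 0

    def test_more_folds_than_samples_rejected(self):
        X, t, e = toy_cohort(9, n=8)
        with pytest.raises(ValueError):
            cross_validate(X, t, e, CoxnetConfig(cv_folds=10))


class TestSelectionAndRisk:
    def test_lambda_max_selects_nothing(self):
        X, t, e = toy_cohort(10)
        path = fit_path(X, t, e, CoxnetConfig())
        sel = select_features(path, path.lambdas[0])
        assert sel.genes == []

    def test_selection_ordered_by_magnitude(self):
        X, t, e = toy_cohort(11, n=80, p=4)
        path = fit_path(X, t, e, CoxnetConfig())
        sel = select_features(path, path.lambdas[-1])
        mags = [abs(v) for v in sel.coefficients]
        assert mags == sorted(mags, reverse=True)

    def test_off_path_lambda_rejected(self):
        X, t, e = toy_cohort(12)
        path = fit_path(X, t, e, CoxnetConfig())
        with pytest.raises(ValueError):
            select_features(path, 123.456)

    def test_zero_beta_unit_risks(self):
        z = pd.DataFrame(
            np.random.default_rng(1).standard_normal((3, 5)),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(5)],
        )
        beta = pd.Series([0.0, 0.0], index=["a", "b"])
        assert np.allclose(relative_risk(beta, z), 1.0)

    def test_doubling_beta_doubles_log_risk(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(
            rng.standard_normal((2, 6)), index=["a", "b"],
            columns=[f"s{i}" for i in range(6)],
        )
        beta = pd.Series([0.4, -0.3], index=["a", "b"])
        r1 = np.log(relative_risk(beta, z))
        r2 = np.log(relative_risk(2 * beta, z))
        assert np.allclose(r2, 2 * r1)

    def test_planted_cohort_risk_anticorrelates_with_survival(self):
        from ironsig import prediction_correlation

        cfg = planted_config(seed=23, n_samples=300)
        expr, clinical, _ = simulate_cohort(cfg)
        z = compute_zscores(expr)
        X, t, e = panel_matrix(z, GenePanel("all", tuple(expr.index)), clinical)
        cv = cross_validate(X, t, e, CoxnetConfig(seed=1))
        risks = relative_risk(cv.selection.coefficients, z)
        unc = clinical[clinical["event"]]
        r2 = prediction_correlation(risks.loc[unc.index], unc["os_months"])
        assert r2 < 0
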