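"""Elastic-net logistic regression: limiting cases against independent
oracles, path behavior, cross-validation contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from trgkit.enet import (cross_validated_auc, fit_elastic_net_logistic,
                         impute_column_means, make_lambda_grid,
                         penalized_objective, single_feature_auc,
                         stratified_folds)


def logistic_data(n=200, p=6, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.0, -1.0, 0.5][: min(3, p)]
    eta = X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    if y.min() == y.max():  # pragma: no cover - seeds chosen to avoid
        y[0] = 1 - y[0]
    return X, y


def ridge_oracle(X, y, lam):
    """Smooth-objective minimizer via BFGS (independent of the CD path)."""
    n, p = X.shape

    def obj(w):
        return penalized_objective(X, y, w[0], w[1:], lam, 0.0)

    res = minimize(obj, np.zeros(p + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 2000})
    return res.x[0], res.x[1:]


def lasso_oracle(X, y, lam):
    """L1 problem via positive/negative coefficient split + L-BFGS-B."""
    n, p = X.shape

    def obj(w):
        beta = w[1:p + 1] - w[p + 1:]
        base = penalized_objective(X, y, w[0], beta, 0.0, 0.5)
        return base + lam * (w[1:].sum())

    bounds = [(None, None)] + [(0, None)] * (2 * p)
    res = minimize(obj, np.zeros(2 * p + 1), method="L-BFGS-B", bounds=bounds,
                   options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000})
    return res.x[0], res.x[1:p + 1] - res.x[p + 1:]


def test_lambda_zero_matches_irls_mle_oracle():
    import statsmodels.api as sm

    X, y = logistic_data()
    model = fit_elastic_net_logistic(X, y, 0.0)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    fitted = np.r_[model.intercept, model.coefficients]
    assert np.max(np.abs(fitted - ref.params)) < 1e-6


def test_huge_lambda_gives_intercept_only_null_model():
    X, y = logistic_data(seed=3)
    model = fit_elastic_net_logistic(X, y, 1e6)
    assert np.all(model.coefficients == 0.0)
    phat = y.mean()
    assert model.intercept == pytest.approx(np.log(phat / (1 - phat)),
                                            abs=1e-8)


def test_row_duplication_leaves_fit_unchanged():
    X, y = logistic_data(n=80, seed=5)
    m1 = fit_elastic_net_logistic(X, y, 0.05)
    m2 = fit_elastic_net_logistic(np.vstack([X, X]), np.r_[y, y], 0.05)
    assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-6)
    assert m1.intercept == pytest.approx(m2.intercept, abs=1e-6)


def test_l1_norm_non_increasing_along_path():
    X, y = logistic_data(n=150, seed=7)
    grid = make_lambda_grid(X, y, 0.5, n_lambda=10)
    norms, model = [], None
    for lam in grid:  # descending lambda
        model = fit_elastic_net_logistic(X, y, lam, 0.5, warm_start=model)
        norms.append(np.abs(model.coefficients * model.feature_scales).sum())
    diffs = np.diff(norms)
    assert np.all(diffs >= -1e-8)
    assert norms[0] == pytest.approx(0.0, abs=1e-10)  # lambda_max kills all


@pytest.mark.parametrize("alpha,oracle", [(0.0, ridge_oracle),
                                          (1.0, lasso_oracle)])
def test_pure_ridge_and_lasso_match_objective_oracles(alpha, oracle):
    X, y = logistic_data(n=120, p=4, seed=9)
    # compare on the standardized scale, where the penalty is applied
    Xs = (X - X.mean(0)) / X.std(0)
    lam = 0.02
    model = fit_elastic_net_logistic(Xs, y, lam, alpha)
    b0_ref, b_ref = oracle(Xs, y, lam)
    obj_fit = penalized_objective(Xs, y, model.intercept, model.coefficients,
                                  lam, alpha)
    obj_ref = penalized_objective(Xs, y, b0_ref, b_ref, lam, alpha)
    assert obj_fit <= obj_ref + 1e-8


def test_errors_on_bad_inputs():
    X, y = logistic_data()
    with pytest.raises(ValueError, match="classes"):
        fit_elastic_net_logistic(X, np.zeros(len(y)), 0.1)
    Xbad = X.copy()
    Xbad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        fit_elastic_net_logistic(Xbad, y, 0.1)


def test_separation_divergence_guard_warns():
    X = np.r_[np.full((10, 1), -1.0), np.full((10, 1), 1.0)]
    X = X + np.random.default_rng(0).normal(0, 0.01, X.shape)
    y = np.r_[np.zeros(10), np.ones(10)]
    with pytest.warns(RuntimeWarning):
        model = fit_elastic_net_logistic(X, y, 0.0)
    assert np.all(np.isfinite(model.coefficients))


def test_stratified_folds_partition_and_balance():
    y = np.r_[np.ones(10), np.zeros(40)]
    folds = stratified_folds(y, 5, seed=1)
    assert sorted(np.unique(folds)) == [0, 1, 2, 3, 4]
    for f in range(5):
        assert y[folds == f].sum() == 2  # positives spread evenly
    with pytest.raises(ValueError, match="fewer"):
        stratified_folds(np.r_[np.ones(3), np.zeros(40)], 5, seed=1)


def test_cv_oracle_feature_and_determinism():
    rng = np.random.default_rng(11)
    n = 120
    y = rng.integers(0, 2, n).astype(float)
    y[:5], y[-5:] = 1, 0
    X = pd.DataFrame({"oracle": y + rng.normal(0, 0.01, n),
                      "noise": rng.normal(size=n)})
    rep1 = cross_validated_auc(X, y, 5, seed=42)
    rep2 = cross_validated_auc(X, y, 5, seed=42)
    assert rep1.cv_auc >= 0.99
    assert rep1.cv_auc == rep2.cv_auc
    assert rep1.chosen_lambda == rep2.chosen_lambda
    assert rep1.fold_assignments == rep2.fold_assignments
    ranks = single_feature_auc(X, y, 5, seed=42)
    assert ranks.index[0] == "oracle" and ranks.iloc[0] >= 0.99
    assert 0.3 <= ranks["noise"] <= 0.7


def test_cv_auc_null_band():
    """Labels independent of X: best-lambda CV AUC stays near 1/2."""
    aucs = []
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        X = rng.normal(size=(400, 10))
        y = (rng.random(400) < 0.5).astype(float)
        aucs.append(cross_validated_auc(X, y, 5, seed=seed).cv_auc)
    assert 0.42 <= float(np.mean(aucs)) <= 0.58


def test_impute_column_means():
    X = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [np.nan] * 3})
    filled, means = impute_column_means(X)
    assert filled["a"].tolist() == [1.0, 2.0, 3.0]
    assert filled["b"].tolist() == [0.0, 0.0, 0.0]
    assert means["a"] == 2.0
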