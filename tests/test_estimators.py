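"""Minimum pseudodistance and BHHJ estimators: recovery, limits, equivariance, contracts."""

import math

import numpy as np
import pytest
from sklearn.base import clone

import picselect as ps
from picselect.estimators import _mpe_objective
from picselect.exceptions import (
    DegenerateDataError,
    DesignMatrixError,
    InsufficientDataError,
)


def test_normal_fit_recovers_truth(rng):
    m0, s0, n = 2.0, 1.5, 500
    fit = ps.fit_normal_mpe(rng.normal(m0, s0, n), gamma=0.2)
    info = ps.asymptotic_info(ps.NormalSpec(m0, s0), 0.2)
    se = np.sqrt(np.diag(info.V) / n)
    assert abs(fit.params.intercept - m0) < 3 * se[0]
    assert abs(fit.params.sigma - s0) < 3 * se[1]
    assert fit.converged


def test_normal_fit_small_gamma_matches_mle(rng):
    x = rng.normal(0.0, 2.0, 200)
    fit = ps.fit_normal_mpe(x, gamma=1e-3)
    assert fit.params.intercept == pytest.approx(x.mean(), abs=1e-3)
    assert fit.params.sigma == pytest.approx(x.std(), abs=1e-3)


def test_normal_fit_affine_equivariance(rng):
    x = rng.normal(1.0, 1.0, 150)
    a, b = -2.0, 3.0
    base = ps.fit_normal_mpe(x, gamma=0.2)
    moved = ps.fit_normal_mpe(a * x + b, gamma=0.2)
    assert moved.params.intercept == pytest.approx(a * base.params.intercept + b, abs=1e-5)
    assert moved.params.sigma == pytest.approx(abs(a) * base.params.sigma, abs=1e-5)


def test_normal_fit_degenerate_sample():
    with pytest.raises(DegenerateDataError):
        ps.fit_normal_mpe(np.full(20, 3.14), gamma=0.2)


def test_regression_small_gamma_matches_ols(rng):
    X = rng.normal(size=(120, 3))
    y = 1.0 + X @ [1.0, -0.5, 2.0] + rng.normal(size=120)
    fit = ps.fit_regression_mpe(y, X, gamma=1e-3)
    ols = np.linalg.lstsq(np.column_stack([np.ones(120), X]), y, rcond=None)[0]
    est = np.append(fit.params.intercept, fit.params.slopes)
    assert np.allclose(est, ols, atol=1e-3)


def test_regression_recovers_truth(rng):
    n = 500
    X = rng.normal(size=(n, 2))
    y = 1.0 + X @ [1.0, 1.0] + rng.normal(size=n)
    fit = ps.fit_regression_mpe(y, X, gamma=0.2)
    # conservative MC band: OLS standard errors inflated for the robust fit
    se = 1.2 / math.sqrt(n)
    est = np.append(fit.params.intercept, fit.params.slopes)
    assert np.all(np.abs(est - 1.0) < 3 * se * np.array([1.0, 1.0, 1.0]) * 1.5)
    assert abs(fit.params.sigma - 1.0) < 0.15


def test_regression_contracts(rng):
    X = rng.normal(size=(50, 2))
    with pytest.raises(DegenerateDataError):
        ps.fit_regression_mpe(1.0 + X[:, 0], X[:, :1], gamma=0.2)  # noiseless
    with pytest.raises(DesignMatrixError):
        ps.fit_regression_mpe(rng.normal(size=50), np.column_stack([X[:, 0], X[:, 0]]), 0.2)
    with pytest.raises(InsufficientDataError):
        ps.fit_regression_mpe(np.arange(4.0), rng.normal(size=(4, 2)), 0.2)


def test_q_statistic_two_routes_agree(rng):
    x = rng.normal(0.0, 1.0, 80)
    fit = ps.fit_normal_mpe(x, gamma=0.25)
    # r_hat is accumulated from the h-weights, independently of the optimizer value
    assert -math.log(fit.r_hat) / fit.gamma == pytest.approx(fit.q_value, abs=1e-10)
    assert ps.q_statistic(fit) == fit.q_value


def test_optimum_not_worse_than_start(rng):
    n = 60
    X = rng.normal(size=(n, 2))
    y = 1.0 + X @ [1.0, 1.0] + rng.normal(size=n) + (rng.random(n) < 0.2) * 8.0
    fit = ps.fit_regression_mpe(y, X, gamma=0.2)
    Xd = np.column_stack([np.ones(n), X])
    coef = np.linalg.lstsq(Xd, y, rcond=None)[0]
    s0 = math.sqrt(np.sum((y - Xd @ coef) ** 2) / n)
    start_value, _ = _mpe_objective(np.append(coef, math.log(s0)), y, Xd, 0.2)
    assert fit.q_value <= start_value + 1e-12


@pytest.mark.parametrize("gamma", [0.01, 0.1, 0.3])
def test_regression_equivariance(gamma, rng):
    n = 100
    X = rng.normal(size=(n, 2))
    y = 0.5 + X @ [1.0, -1.0] + rng.normal(size=n)
    a, c = 1.7, np.array([0.4, -0.8])
    base = ps.fit_regression_mpe(y, X, gamma)
    moved = ps.fit_regression_mpe(a * y + X @ c, X, gamma)
    assert moved.params.intercept == pytest.approx(a * base.params.intercept, abs=1e-4)
    assert np.allclose(moved.params.slopes, a * base.params.slopes + c, atol=1e-4)
    assert moved.params.sigma == pytest.approx(a * base.params.sigma, abs=1e-4)


def test_mdpd_small_alpha_matches_ols(rng):
    X = rng.normal(size=(100, 2))
    y = 1.0 + X @ [2.0, -1.0] + rng.normal(size=100)
    est = ps.MDPDRegressor(alpha=1e-3).fit(X, y)
    ols = np.linalg.lstsq(np.column_stack([np.ones(100), X]), y, rcond=None)[0]
    assert np.allclose(np.append(est.intercept_, est.coef_), ols, atol=1e-3)
    assert est.scale_ == pytest.approx(
        math.sqrt(np.sum((y - np.column_stack([np.ones(100), X]) @ ols) ** 2) / 100),
        abs=1e-3,
    )


def test_robustness_to_shifted_outliers(rng):
    # the working reason for gamma > 0: a shifted cluster barely moves the fit
    n = 200
    X = rng.normal(size=(n, 1))
    y = 1.0 + X[:, 0] + rng.normal(size=n)
    y_cont = y.copy()
    y_cont[: n // 10] += 12.0
    robust = ps.fit_regression_mpe(y_cont, X, gamma=0.3)
    mle = ps.fit_regression_mpe(y_cont, X, gamma=1e-3)
    clean = ps.fit_regression_mpe(y, X, gamma=0.3)
    assert abs(robust.params.intercept - clean.params.intercept) < 0.3 * abs(
        mle.params.intercept - clean.params.intercept
    )
    assert robust.params.sigma < mle.params.sigma


def test_sklearn_protocol(rng):
    X = rng.normal(size=(80, 2))
    y = 1.0 + X @ [1.0, 1.0] + rng.normal(size=80)
    est = ps.PseudodistanceRegressor(gamma=0.15)
    cloned = clone(est)
    assert cloned.get_params()["gamma"] == 0.15
    cloned.set_params(gamma=0.2).fit(X, y)
    pred = cloned.predict(X)
    assert pred.shape == (80,)
    assert cloned.score(X, y) > 0.5
    norm = ps.NormalLocationScale(gamma=0.2).fit(rng.normal(2.0, 1.0, size=(60, 1)))
    assert norm.location_ == pytest.approx(2.0, abs=0.5)
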