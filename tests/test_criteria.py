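"""Information criteria, candidate enumeration and all-subsets selection."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import picselect as ps
from picselect.criteria import CandidateModel, _pic_penalty_factor
from picselect.estimators import FitResult, RegressionParams
from picselect.exceptions import (
    DesignMatrixError,
    DomainError,
    InsufficientDataError,
)


def make_fit(q_value, p, n, gamma, sigma=1.0):
    params = RegressionParams(intercept=0.0, slopes=np.ones(p) if p else [], sigma=sigma)
    if p == 0:
        params = RegressionParams(intercept=0.0, slopes=np.empty(0), sigma=sigma)
    return FitResult(params=params, gamma=gamma, q_value=q_value, n=n,
                     converged=True, n_restarts_used=1,
                     r_hat=math.exp(-gamma * q_value))


# ---------------------------------------------------------------- enumeration

def test_enumerate_counts():
    assert len(ps.enumerate_candidates(4, 1)) == 15
    assert len(ps.enumerate_candidates(4, 2)) == 11
    assert len(ps.enumerate_candidates(1, 1)) == 1
    with pytest.raises(DomainError):
        ps.enumerate_candidates(4, 0)
    with pytest.raises(DomainError):
        ps.enumerate_candidates(4, 5)


def test_enumerate_order_deterministic():
    labels = [m.label for m in ps.enumerate_candidates(3, 1)]
    assert labels == ["X1", "X2", "X3", "X1,X2", "X1,X3", "X2,X3", "X1,X2,X3"]


def test_candidate_model_validation():
    with pytest.raises(DomainError):
        CandidateModel(())
    with pytest.raises(DomainError):
        CandidateModel((1, 1))
    assert CandidateModel((3, 1)).label == "X1,X3"


# ------------------------------------------------------------------- PIC

def test_pic_penalty_factor_limit():
    # (g+1)^2/(2g+1)^(3/2) -> 1, so the first penalty tends to d/n
    assert _pic_penalty_factor(1e-9) == pytest.approx(1.0, abs=1e-7)
    assert _pic_penalty_factor(0.2) == pytest.approx(0.8693015191493314)


def test_pic_normal_ratio_matches_quadrature():
    spec, g = ps.NormalSpec(0.0, 1.0), 0.2
    num, _ = quad(lambda x: spec.pdf(x) ** (2 * g + 1), -np.inf, np.inf,
                  epsabs=1e-12, epsrel=1e-12)
    den, _ = quad(lambda x: spec.pdf(x) ** (g + 1), -np.inf, np.inf,
                  epsabs=1e-12, epsrel=1e-12)
    closed = ps.normal_power_integral(spec, 2 * g + 1) / ps.normal_power_integral(
        spec, g + 1) ** 2
    assert closed == pytest.approx(num / den**2, abs=1e-8)
    assert closed == pytest.approx((g + 1) / math.sqrt(2 * g + 1))


def test_pic_normal_correction_hand_arithmetic():
    # gamma=0.2, n=20, d=2: independently computed penalty sum
    score = ps.pic_normal(make_fit(0.0, 0, 20, 0.2))
    assert score.value == pytest.approx(0.08515701370565565, abs=1e-12)


def test_pic_normal_rejects_regression_fit():
    with pytest.raises(DomainError):
        ps.pic_normal(make_fit(0.0, 2, 20, 0.2))


def test_pic_regression_variants_differ_by_model_free_constant(hald_data):
    y, X = hald_data
    offsets = []
    for model in ps.enumerate_candidates(4, 2):
        fit = ps.fit_regression_mpe(y, model.columns(X), 0.2)
        red = ps.pic_regression(fit, "reduced", model).value
        full = ps.pic_regression(fit, "full", model).value
        offsets.append(full - red)
    assert np.ptp(offsets) < 1e-12


@pytest.mark.parametrize("gamma", [0.01, 0.05, 0.1, 0.2, 0.3])
def test_pic_regression_per_parameter_penalty_positive(gamma):
    n = 50
    low = ps.pic_regression(make_fit(1.0, 1, n, gamma)).value
    high = ps.pic_regression(make_fit(1.0, 2, n, gamma)).value
    assert high > low  # strictly positive penalty per extra parameter


def test_pic_regression_penalty_coefficient_hand_arithmetic():
    # per-parameter coefficient (n-independent): c + (1 - rho)/(2*gamma) at gamma=0.2
    g, n = 0.2, 40
    delta = (ps.pic_regression(make_fit(0.0, 2, n, g)).value
             - ps.pic_regression(make_fit(0.0, 1, n, g)).value)
    assert delta * n == pytest.approx(1.0547512697179526, abs=1e-12)


def test_pic_gamma_range_warning():
    with pytest.warns(UserWarning):
        ps.pic_regression(make_fit(0.0, 1, 20, 0.45))


# ------------------------------------------------------------------ AIC / BIC

def test_aic_bic_toy_hand_arithmetic():
    # six printed points, one regressor; RSS from the explicit 2x2 normal equations
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.1, 2.9, 5.2, 6.8, 9.1, 11.2])
    n = 6
    sxx = np.sum((x - x.mean()) ** 2)
    beta = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    alpha = y.mean() - beta * x.mean()
    rss = float(np.sum((y - alpha - beta * x) ** 2))
    model = CandidateModel((1,))
    assert ps.aic(y, x[:, None], model).value == pytest.approx(
        n * math.log(rss / n) + 2 * 1 + 2, abs=1e-10
    )
    assert ps.bic(y, x[:, None], model).value == pytest.approx(
        n * math.log(rss / n) + 3 * math.log(n), abs=1e-10
    )


@pytest.mark.parametrize("n", [13, 50, 200, 500])
def test_bic_penalizes_more_than_aic_for_log_n_above_two(n, rng):
    X = rng.normal(size=(n, 3))
    y = 1.0 + X @ [1.0, 1.0, 0.0] + rng.normal(size=n)
    small, big = CandidateModel((1,)), CandidateModel((1, 2, 3))
    d_aic = ps.aic(y, X, big).value - ps.aic(y, X, small).value
    d_bic = ps.bic(y, X, big).value - ps.bic(y, X, small).value
    assert d_bic > d_aic  # per-parameter log(n) > 2


def test_aic_duplicate_column_design_error(rng):
    X = rng.normal(size=(20, 1))
    y = X[:, 0] + rng.normal(size=20)
    with pytest.raises((DesignMatrixError, ValueError)):
        ps.aic(y, np.column_stack([X, X]), CandidateModel((1, 2)))


def test_aic_insufficient_data():
    with pytest.raises(InsufficientDataError):
        ps.aic(np.arange(3.0), np.eye(3)[:, :2], CandidateModel((1, 2)))


# ---------------------------------------------------------------------- MDIC

def test_mdic_penalty_monotone_in_p():
    a = 0.25
    pen = [(2 * math.pi) ** (-a / 2) * (1 + a) ** (2 + p / 2) * p for p in range(1, 6)]
    assert np.all(np.diff(pen) > 0)


def test_mdic_value_formula(rng):
    # MDIC recomputed independently from the fitted BHHJ parameters
    X = rng.normal(size=(40, 2))
    y = 1.0 + X @ [1.0, 1.0] + rng.normal(size=40)
    model = CandidateModel((1, 2))
    a = 0.25
    score = ps.mdic(y, X, model, alpha=a)
    est = ps.MDPDRegressor(alpha=a).fit(X, y)
    e = y - est.predict(X)
    f = np.exp(-0.5 * (e / est.scale_) ** 2) / (est.scale_ * math.sqrt(2 * math.pi))
    expected = 40 * (-(1 + 1 / a) * np.mean(f**a)) + (2 * math.pi) ** (-a / 2) * (
        1 + a) ** (2 + 2 / 2) * 2
    assert score.value == pytest.approx(expected, rel=1e-6)


# ------------------------------------------------------------------ selection

def test_select_model_single_candidate(hald_data):
    y, X = hald_data
    only = [CandidateModel((1, 2))]
    result = ps.select_model(y, X, "bic", only)
    assert result.chosen == only[0]
    assert len(result.ranking) == 1


def test_select_model_order_invariance(hald_data):
    y, X = hald_data
    cands = ps.enumerate_candidates(4, 2)
    forward = ps.select_model(y, X, "aic", cands)
    backward = ps.select_model(y, X, "aic", list(reversed(cands)))
    assert forward.chosen == backward.chosen
    assert [s.model for s in forward.ranking] == [s.model for s in backward.ranking]


def test_select_model_deterministic(hald_data):
    y, X = hald_data
    a = ps.select_model(y, X, "pic", gamma=0.2, min_size=2)
    b = ps.select_model(y, X, "pic", gamma=0.2, min_size=2)
    assert a.chosen == b.chosen
    assert [s.value for s in a.ranking] == [s.value for s in b.ranking]


def test_select_model_error_carries_label():
    y = np.arange(5.0)
    X = np.column_stack([np.arange(5.0), np.ones(5)])
    with pytest.raises(Exception) as excinfo:
        ps.select_model(y, X, "aic", [CandidateModel((1, 2))])
    assert "X1,X2" in "".join(getattr(excinfo.value, "__notes__", []))


def test_subset_selector_sklearn(rng):
    n = 200
    X = rng.normal(size=(n, 4))
    y = 1.0 + X @ [1.0, 1.0, 0.0, 0.0] + rng.normal(size=n)
    sel = ps.SubsetSelector(criterion="bic").fit(X, y)
    assert sel.best_model_.indices == (1, 2)
    assert list(sel.get_support()) == [True, True, False, False]
    # PIC never drops a strong true regressor
    sel_pic = ps.SubsetSelector(criterion="pic", gamma=0.2).fit(X, y)
    assert {1, 2} <= set(sel_pic.best_model_.indices)
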