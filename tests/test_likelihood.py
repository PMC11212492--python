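"""Likelihood engine against independent oracles.

Dense multivariate-normal computations, Monte-Carlo rectangle estimates,
numeric mixed partials of the joint CDF, and finite-difference gradients
all re-derive what the vectorized engine computes.
"""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, ndtri

from mtram.basis import BasisSpec, basis_deriv_matrix, basis_matrix
from mtram.covariance import RandomEffectDesign
from mtram.data import ClusteredData
from mtram.likelihood import (ParameterVector, TransformationLikelihood,
                              latent_transform, log_normal_rectangle,
                              mvn_rectangle)

from conftest import finite_difference_gradient


# ---------------------------------------------------------------- latent map
def test_latent_transform_probit_reduces_to_shifted_h(small_exact, intercept_design):
    data, basis, pv = small_exact
    z = latent_transform(data.y[:3], pv, link="probit", basis=basis,
                        design=intercept_design, X=data.X[:3])
    h = basis_matrix(basis, data.y[:3]) @ pv.theta
    assert np.allclose(z, h - data.X[:3] @ pv.beta, atol=1e-14)


def test_latent_transform_infinite_bounds(small_exact, intercept_design):
    _, basis, pv = small_exact
    z = latent_transform([-np.inf, np.inf], pv, link="logit", basis=basis,
                        design=intercept_design, X=np.zeros((2, 2)))
    assert np.isneginf(z[0]) and np.isposinf(z[1])


def test_latent_transform_logit_scalar_composition(small_exact, intercept_design):
    data, basis, pv = small_exact
    y0, x0 = data.y[0], data.X[0]
    z = latent_transform([y0], pv, link="logit", basis=basis,
                        design=intercept_design, X=x0[None, :])
    d = np.sqrt(1 + pv.gamma[0] ** 2)
    h = (basis_matrix(basis, [y0]) @ pv.theta).item()
    expected = d * ndtri(expit((h - x0 @ pv.beta) / d))
    assert z[0] == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------- continuous loglik
def test_continuous_probit_equals_dense_mvn(small_exact, intercept_design):
    data, basis, pv = small_exact
    eng = TransformationLikelihood(data, "probit", basis, intercept_design)
    h = basis_matrix(basis, data.y) @ pv.theta
    hp = basis_deriv_matrix(basis, data.y) @ pv.theta
    z = h - data.X @ pv.beta
    Sigma = pv.gamma[0] ** 2 * np.ones((3, 3)) + np.eye(3)
    mvn = stats.multivariate_normal(np.zeros(3), Sigma)
    expected = sum(mvn.logpdf(z[data.cluster == i]) + np.log(hp[data.cluster == i]).sum()
                   for i in range(4))
    assert eng.loglik(pv) == pytest.approx(expected, abs=1e-10)


def test_continuous_independence_is_univariate_model(small_exact, intercept_design):
    # gamma = 0 with the linear basis reduces to iid normal densities
    data, _, _ = small_exact
    sigma, alpha = 1.7, 2.0
    basis = BasisSpec("linear", support=(-100, 100))
    pv = ParameterVector(np.array([1 / sigma, alpha / sigma]),
                         np.zeros(2), np.array([0.0]))
    eng = TransformationLikelihood(data, "probit", basis, intercept_design)
    expected = stats.norm(alpha, sigma).logpdf(data.y).sum()
    assert eng.loglik(pv) == pytest.approx(expected, abs=1e-10)


def test_continuous_logit_matches_mixed_partial_of_joint_cdf(intercept_design):
    # Ni=2 logistic case: density from numerically differentiating the
    # copula joint CDF, agreement to 1e-4
    rng = np.random.default_rng(3)
    y = np.array([4.0, 6.5])
    X = rng.uniform(size=(2, 1))
    data = ClusteredData(lower=y, upper=y.copy(), X=X, cluster=[0, 0])
    basis = BasisSpec("bernstein", 3, (1.0, 10.0))
    pv = ParameterVector(np.array([-2.0, -0.5, 0.5, 2.5]),
                         np.array([0.8]), np.array([1.2]))
    eng = TransformationLikelihood(data, "logit", basis, intercept_design)

    d = np.sqrt(1 + pv.gamma[0] ** 2)
    Sigma = pv.gamma[0] ** 2 * np.ones((2, 2)) + np.eye(2)

    def joint_cdf(y1, y2):
        h = basis_matrix(basis, [y1, y2]) @ pv.theta
        z = d * ndtri(expit((h - X @ pv.beta) / d))
        return stats.multivariate_normal.cdf(z, np.zeros(2), Sigma,
                                             abseps=1e-13, releps=0.0)

    h = 2e-3
    dens = (joint_cdf(y[0] + h, y[1] + h) - joint_cdf(y[0] + h, y[1] - h)
            - joint_cdf(y[0] - h, y[1] + h) + joint_cdf(y[0] - h, y[1] - h)) / (4 * h * h)
    assert eng.loglik(pv) == pytest.approx(np.log(dens), abs=1e-4)


def test_continuous_jacobian_affine_invariance(small_exact, intercept_design):
    # rescaling the response with matched h values changes the loglik by the
    # constant log-Jacobian n*log(1/a) only
    data, _, pv0 = small_exact
    a, b = 2.5, -1.0
    basis = BasisSpec("linear", support=(-1000, 1000))
    theta = np.array([0.9, 1.1])
    pv = ParameterVector(theta, pv0.beta, pv0.gamma)
    eng = TransformationLikelihood(data, "logit", basis, intercept_design)
    y2 = a * data.y + b
    data2 = ClusteredData(lower=y2, upper=y2.copy(), X=data.X.copy(),
                          cluster=data.cluster.copy())
    theta2 = np.array([theta[0] / a, theta[1] + theta[0] * b / a])
    pv2 = ParameterVector(theta2, pv0.beta, pv0.gamma)
    eng2 = TransformationLikelihood(data2, "logit", basis, intercept_design)
    assert eng2.loglik(pv2) == pytest.approx(eng.loglik(pv) - data.n_obs * np.log(a),
                                             abs=1e-9)


# ----------------------------------------------------------------- scores
@pytest.mark.parametrize("link", ["probit", "logit", "cloglog"])
def test_score_continuous_matches_finite_differences(small_exact, intercept_design, link):
    data, basis, pv = small_exact
    eng = TransformationLikelihood(data, link, basis, intercept_design)
    g = eng.score(pv)
    g_fd = finite_difference_gradient(eng.loglik, pv.flat)
    assert np.max(np.abs(g - g_fd) / (np.abs(g_fd) + 1e-8)) < 1e-5


def test_score_continuous_intercept_slope(small_exact):
    data, basis, pv0 = small_exact
    t = np.tile(np.arange(3.0), 4)
    data_t = ClusteredData(lower=data.y, upper=data.y.copy(), X=data.X.copy(),
                           cluster=data.cluster.copy(), time=t)
    pv = ParameterVector(pv0.theta, pv0.beta, np.array([0.8, -0.2, 0.5]))
    eng = TransformationLikelihood(data_t, "logit", basis,
                                   RandomEffectDesign("intercept_slope"))
    g = eng.score(pv)
    g_fd = finite_difference_gradient(eng.loglik, pv.flat)
    assert np.max(np.abs(g - g_fd) / (np.abs(g_fd) + 1e-8)) < 1e-5


def test_score_continuous_normal_independence_closed_form(small_exact, intercept_design):
    # F = probit, gamma = 0, linear basis: score has the textbook normal form
    data, _, _ = small_exact
    sigma, alpha, beta = 1.4, 1.0, np.array([0.5, -0.3])
    basis = BasisSpec("linear", support=(-100, 100))
    pv = ParameterVector(np.array([1 / sigma, alpha / sigma]), beta, np.array([0.0]))
    eng = TransformationLikelihood(data, "probit", basis, intercept_design)
    g = eng.score(pv)
    r = data.y * pv.theta[0] - pv.theta[1] - data.X @ beta  # standardized residual
    # d/dtheta1 = sum(y*(-r)) + n/theta1 ; d/dtheta2 = sum(r); d/dbeta = X'r
    assert g[0] == pytest.approx(float(-(data.y * r).sum() + data.n_obs / pv.theta[0]), rel=1e-9)
    assert g[1] == pytest.approx(float(r.sum()), rel=1e-9)
    assert np.allclose(g[2:4], data.X.T @ r, rtol=1e-9)


def test_score_censored_matches_finite_differences(small_censored, intercept_design):
    data, basis, pv = small_censored
    eng = TransformationLikelihood(data, "logit", basis, intercept_design)
    g = eng.score(pv)
    g_fd = finite_difference_gradient(eng.loglik, pv.flat)
    assert np.max(np.abs(g - g_fd) / (np.abs(g_fd) + 1e-8)) < 1e-5


# ------------------------------------------------------------ mvn rectangle
def test_mvn_rectangle_independence_is_product(intercept_design):
    lo = np.array([-1.0, -np.inf, 0.2])
    hi = np.array([0.5, 1.0, np.inf])
    p = mvn_rectangle(lo, hi, intercept_design, [0.0])
    expected = np.prod(stats.norm.cdf(hi) - stats.norm.cdf(lo))
    assert p == pytest.approx(expected, abs=1e-12)


def test_mvn_rectangle_total_mass(intercept_design):
    p = mvn_rectangle(np.full(5, -np.inf), np.full(5, np.inf),
                      intercept_design, [1.5])
    assert p == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("gamma1", [0.5, 1.0, 3.0])
def test_mvn_rectangle_matches_monte_carlo(intercept_design, gamma1):
    # 1e7-draw Monte-Carlo oracle of the compound-symmetry rectangle
    rng = np.random.default_rng(17)
    lo = np.array([-1.2, -0.4, -np.inf, 0.0, -2.0])
    hi = np.array([0.8, 1.5, 1.0, np.inf, 0.5])
    p = mvn_rectangle(lo, hi, intercept_design, [gamma1], check=True)
    n_total, hits = 10_000_000, 0
    for _ in range(10):
        n = n_total // 10
        z = gamma1 * rng.standard_normal((n, 1)) + rng.standard_normal((n, 5))
        hits += int(np.all((z > lo) & (z <= hi), axis=1).sum())
    p_mc = hits / n_total
    se = np.sqrt(p_mc * (1 - p_mc) / n_total)
    assert abs(p - p_mc) < 3 * se


def test_mvn_rectangle_monotone_in_rectangle(intercept_design, rng):
    lo = np.array([-1.0, -0.5, 0.0])
    hi = np.array([0.5, 1.0, 1.5])
    p0 = mvn_rectangle(lo, hi, intercept_design, [1.0])
    p1 = mvn_rectangle(lo - 0.3, hi + 0.2, intercept_design, [1.0])
    assert p1 >= p0


def test_mvn_rectangle_intercept_slope_dense_oracle():
    des = RandomEffectDesign("intercept_slope")
    t = np.array([0.0, 1.0, 2.0])
    gamma = np.array([0.8, 0.3, 0.6])
    lo = np.array([-1.0, -0.5, -2.0])
    hi = np.array([1.0, 2.0, 0.5])
    p = mvn_rectangle(lo, hi, des, gamma, time=t, n_nodes=60)
    L = np.array([[0.8, 0.0], [0.3, 0.6]])
    U = np.column_stack([np.ones(3), t])
    Sigma = U @ L @ L.T @ U.T + np.eye(3)
    p_or = stats.multivariate_normal.cdf(
        hi, np.zeros(3), Sigma, lower_limit=lo, abseps=1e-10, releps=0.0)
    assert p == pytest.approx(p_or, abs=5e-7)


# ------------------------------------------------------- censored loglik
def test_censored_single_binary_is_marginal_probability(intercept_design):
    # Ni=1: the rectangle collapses to the closed-form marginal P(Y=1|x)
    alpha, beta, g1 = 0.4, np.array([1.0]), 1.3
    x = np.array([[0.6]])
    data = ClusteredData(lower=[0.0], upper=[np.inf], X=x, cluster=[0])
    basis = BasisSpec("binary_intercept")
    pv = ParameterVector(np.array([alpha]), beta, np.array([g1]))
    eng = TransformationLikelihood(data, "logit", basis, intercept_design)
    expected = 1.0 - expit((alpha - x[0] @ beta) / np.sqrt(g1 ** 2 + 1.0))
    assert np.exp(eng.loglik(pv)) == pytest.approx(expected, rel=1e-10)


def test_censored_independence_reduces_to_univariate(small_censored, intercept_design):
    data, basis, pv0 = small_censored
    pv = ParameterVector(pv0.theta, pv0.beta, np.array([0.0]))
    eng = TransformationLikelihood(data, "logit", basis, intercept_design)
    h_lo = basis_matrix(basis, data.lower) @ pv.theta
    h_up = basis_matrix(basis, data.upper) @ pv.theta
    eta_lo = h_lo - data.X @ pv.beta
    eta_up = h_up - data.X @ pv.beta
    expected = np.log(expit(eta_up) - expit(eta_lo)).sum()
    assert eng.loglik(pv) == pytest.approx(expected, abs=1e-10)


def test_censored_matches_dense_mvn_rectangle(small_censored, intercept_design):
    data, basis, pv = small_censored
    eng = TransformationLikelihood(data, "logit", basis, intercept_design)
    ll = eng.cluster_loglik(pv)
    Sigma = pv.gamma[0] ** 2 * np.ones((3, 3)) + np.eye(3)
    for i in range(data.n_clusters):
        sel = data.cluster == i
        zl = latent_transform(data.lower[sel], pv, link="logit", basis=basis,
                             design=intercept_design, X=data.X[sel])
        zu = latent_transform(data.upper[sel], pv, link="logit", basis=basis,
                             design=intercept_design, X=data.X[sel])
        p = stats.multivariate_normal.cdf(zu, np.zeros(3), Sigma,
                                          lower_limit=zl, abseps=1e-12, releps=0.0)
        assert ll[i] == pytest.approx(np.log(p), abs=5e-6)


def test_censored_shrinking_intervals_approach_continuous(intercept_design):
    # discretization consistency on Ni=2 clusters at delta = 1e-3, 1e-4
    rng = np.random.default_rng(11)
    y = rng.chisquare(5, 4)
    X = rng.uniform(size=(4, 1))
    cl = [0, 0, 1, 1]
    basis = BasisSpec("bernstein", 3, (float(y.min() - 1), float(y.max() + 1)))
    pv = ParameterVector(np.array([-2.0, -1.0, 0.5, 2.0]), np.array([0.7]),
                         np.array([1.0]))
    data_c = ClusteredData(lower=y, upper=y.copy(), X=X, cluster=cl)
    ll_cont = TransformationLikelihood(data_c, "logit", basis, intercept_design).loglik(pv)
    errs = []
    for delta in (1e-3, 1e-4):
        data_i = ClusteredData(lower=y - delta, upper=y + delta, X=X, cluster=cl)
        ll_int = TransformationLikelihood(data_i, "logit", basis,
                                          intercept_design).loglik(pv)
        errs.append(abs(ll_int - 4 * np.log(2 * delta) - ll_cont))
    assert errs[1] < errs[0] and errs[1] < 1e-4


def test_censored_partition_mass_sums_to_one(intercept_design):
    # probit, Ni=2: probabilities over a partition of the plane add to 1
    edges = np.concatenate([[-np.inf], np.linspace(-3, 3, 13), [np.inf]])
    basis = BasisSpec("linear", support=(-100, 100))
    pv = ParameterVector(np.array([1.0, 0.0]), np.zeros(0), np.array([1.0]))
    total = 0.0
    for i in range(len(edges) - 1):
        for j in range(len(edges) - 1):
            lo = np.array([edges[i], edges[j]])
            hi = np.array([edges[i + 1], edges[j + 1]])
            data = ClusteredData(lower=lo, upper=hi, X=np.zeros((2, 0)), cluster=[0, 0])
            eng = TransformationLikelihood(data, "probit", basis, intercept_design)
            total += np.exp(eng.loglik(pv))
    assert total == pytest.approx(1.0, abs=1e-8)


def test_mixed_exact_and_censored_rejected(small_exact):
    data, _, _ = small_exact
    lower = data.y.copy()
    upper = data.y.copy()
    upper[0] += 1.0  # one interval row among exact rows
    with pytest.raises(ValueError, match="mixing exact and censored"):
        ClusteredData(lower=lower, upper=upper, X=data.X, cluster=data.cluster
                      ).validate_kind("censored")


def test_log_normal_rectangle_extreme_tails():
    a = np.array([10.0, -np.inf, 30.0])
    b = np.array([11.0, -10.0, 31.0])
    lr = log_normal_rectangle(a, b)
    assert np.all(np.isfinite(lr))
    expected = stats.norm.logcdf(-30.0)  # dominant term of the last cell
    assert lr[2] == pytest.approx(expected, rel=1e-2)
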