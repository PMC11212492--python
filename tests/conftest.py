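import numpy as np
import pytest

from mtram.basis import BasisSpec
from mtram.covariance import RandomEffectDesign
from mtram.data import ClusteredData
from mtram.estimation import ModelSpec, fit_mtram
from mtram.likelihood import ParameterVector, TransformationLikelihood
from mtram.simulate import DGPConfig, dichotomize, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_exact():
    """12 exact chi-square observations in 4 clusters with 2 covariates."""
    rng = np.random.default_rng(7)
    y = rng.chisquare(5, 12)
    X = rng.uniform(size=(12, 2))
    cluster = np.repeat(np.arange(4), 3)
    data = ClusteredData(lower=y, upper=y.copy(), X=X, cluster=cluster)
    basis = BasisSpec("bernstein", 4, (float(y.min()), float(y.max())))
    theta = np.cumsum([0.1, 0.5, 0.4, 0.3, 0.6])
    pv = ParameterVector(theta, np.array([0.3, -0.2]), np.array([0.8]))
    return data, basis, pv


@pytest.fixture(scope="session")
def small_censored(small_exact):
    data, basis, pv = small_exact
    return (ClusteredData(lower=data.y - 0.3, upper=data.y + 0.4,
                          X=data.X.copy(), cluster=data.cluster.copy()),
            basis, pv)


@pytest.fixture(scope="session")
def intercept_design():
    return RandomEffectDesign("intercept")


@pytest.fixture(scope="session")
def dgp_continuous_fit():
    """One replicate of the continuous logistic-copula world, fitted."""
    data = simulate_dataset(DGPConfig(gamma1=1.0, seed=42))
    fit = fit_mtram(data, ModelSpec(link="logit", basis_kind="bernstein", order=6),
                    compute_vcov=True)
    return data, fit


@pytest.fixture(scope="session")
def dgp_binary_fit():
    data = dichotomize(simulate_dataset(DGPConfig(gamma1=1.0, seed=42)))
    fit = fit_mtram(data, ModelSpec(link="logit", basis_kind="binary_intercept"),
                    compute_vcov=True)
    return data, fit


def finite_difference_gradient(f, x, h=1e-6):
    g = np.zeros_like(x)
    for k in range(x.shape[0]):
        xp, xm = x.copy(), x.copy()
        xp[k] += h
        xm[k] -= h
        g[k] = (f(xp) - f(xm)) / (2 * h)
    return g
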