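"""Marginal distributions and effects implied by a fitted joint model.

The Gaussian copula with transformation-model margins gives the marginal
distribution in closed form,

    P(Y <= y | x, u) = F( (a(y)'theta - x'beta) / sqrt(u'LL'u + 1) ),

so the fixed effects divided by the scale factor sqrt(u'LL'u + 1) are
directly interpretable on the scale named by the link (log-odds ratio,
log-hazard ratio, ...).  Confidence intervals for nonlinear functionals of
(theta, beta, gamma) -- shrunken effects, marginal hazard ratios, the
probabilistic index -- are obtained by sampling from the asymptotic joint
normal distribution of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .covariance import marginal_scale
from .basis import basis_matrix
from .estimation import FittedMTRAM
from .likelihood import ParameterVector

__all__ = ["MarginalEffect", "marginal_cdf", "marginal_effects", "simulate_ci",
           "probabilistic_index"]


@dataclass(frozen=True)
class MarginalEffect:
    """Shrunken marginal coefficients mu = beta / sqrt(u'LL'u + 1)."""

    mu: np.ndarray
    u: np.ndarray
    scale_name: str


def _scale(fit: FittedMTRAM, u) -> float:
    u = np.ones(fit.design.R) if u is None else np.atleast_1d(np.asarray(u, float))
    return marginal_scale(u, fit.params.gamma)


def marginal_cdf(fit: FittedMTRAM, y, x=None, u=None, stratum: int = 0):
    """Marginal distribution function at response values y, covariates x and
    random-effect design row u (default: the intercept design u = 1)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    pv = fit.params
    Q = pv.beta.shape[0]
    x = np.zeros(Q) if x is None else np.asarray(x, dtype=float)
    s = _scale(fit, u)
    P = fit.basis.n_param
    theta = pv.theta[stratum * P:(stratum + 1) * P]
    out = np.empty_like(y)
    fin = np.isfinite(y)
    if np.any(fin):
        h = basis_matrix(fit.basis, y[fin]) @ theta
        out[fin] = fit.link.cdf((h - x @ pv.beta) / s)
    out[np.isneginf(y)] = 0.0
    out[np.isposinf(y)] = 1.0
    return out if out.shape != (1,) else float(out[0])


def marginal_effects(fit: FittedMTRAM, u=None) -> MarginalEffect:
    """mu = beta / sqrt(u'LL'u + 1); equals beta when the latent correlation
    vanishes and shrinks toward zero as |gamma_1| grows."""
    u_arr = np.ones(fit.design.R) if u is None else np.atleast_1d(np.asarray(u, float))
    s = _scale(fit, u_arr)
    return MarginalEffect(mu=fit.params.beta / s, u=u_arr,
                          scale_name=fit.link.scale_name)


def _truncate_gamma_draws(draws: np.ndarray, n_theta: int, n_beta: int,
                          R: int) -> np.ndarray:
    diag = np.array([0]) if R == 1 else np.array([0, 2])
    cols = n_theta + n_beta + diag
    draws[:, cols] = np.maximum(draws[:, cols], 0.0)
    return draws


def simulate_ci(fit: FittedMTRAM, functional, B: int = 10_000,
                level: float = 0.95, seed=None,
                return_draws: bool = False):
    """Percentile confidence interval for ``functional(ParameterVector)``.

    Draws B samples from N(estimates, vcov), truncates the diagonal
    covariance parameters at the independence boundary, applies the
    functional, and returns the (1-level)/2 and 1-(1-level)/2 empirical
    quantiles.  The functional may return a scalar or a vector.
    """
    rng = np.random.default_rng(seed)
    x0 = fit.params.flat
    V = fit.vcov
    draws = rng.multivariate_normal(x0, V, size=B, check_valid="ignore",
                                    method="cholesky" if _chol_ok(V) else "svd")
    n_theta, n_beta = fit.n_theta, fit.params.beta.shape[0]
    draws = _truncate_gamma_draws(draws, n_theta, n_beta, fit.design.R)
    vals = []
    n_fail = 0
    for row in draws:
        pv = ParameterVector.from_flat(row, n_theta, n_beta)
        try:
            vals.append(np.atleast_1d(np.asarray(functional(pv), dtype=float)))
        except Exception:
            n_fail += 1
    if n_fail > 0.01 * B:
        raise RuntimeError(f"functional failed on {n_fail}/{B} draws")
    vals = np.asarray(vals)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(vals, alpha, axis=0)
    hi = np.quantile(vals, 1.0 - alpha, axis=0)
    lo = float(lo[0]) if lo.shape == (1,) else lo
    hi = float(hi[0]) if hi.shape == (1,) else hi
    if return_draws:
        return (lo, hi), vals
    return lo, hi


def marginal_effect_cis(fit: FittedMTRAM, u=None, B: int = 10_000,
                        level: float = 0.95, seed=None) -> np.ndarray:
    """Vectorized percentile CIs for all shrunken effects mu; returns (Q, 2).

    Equivalent to ``simulate_ci`` with the marginal-effect functional but
    evaluated on all draws at once (the study harness calls this thousands
    of times).
    """
    rng = np.random.default_rng(seed)
    x0 = fit.params.flat
    V = fit.vcov
    draws = rng.multivariate_normal(x0, V, size=B, check_valid="ignore",
                                    method="cholesky" if _chol_ok(V) else "svd")
    n_theta, n_beta = fit.n_theta, fit.params.beta.shape[0]
    draws = _truncate_gamma_draws(draws, n_theta, n_beta, fit.design.R)
    u_arr = np.ones(fit.design.R) if u is None else np.atleast_1d(np.asarray(u, float))
    betas = draws[:, n_theta:n_theta + n_beta]
    gammas = draws[:, n_theta + n_beta:]
    scales = np.empty(draws.shape[0])
    if fit.design.R == 1:
        scales = np.sqrt(gammas[:, 0] ** 2 * u_arr[0] ** 2 + 1.0)
    else:
        # u'L with lower-triangular row-wise fill [[g1,0],[g2,g3]]
        v1 = u_arr[0] * gammas[:, 0] + u_arr[1] * gammas[:, 1]
        v2 = u_arr[1] * gammas[:, 2]
        scales = np.sqrt(v1 ** 2 + v2 ** 2 + 1.0)
    mus = betas / scales[:, None]
    alpha = (1.0 - level) / 2.0
    return np.column_stack([np.quantile(mus, alpha, axis=0),
                            np.quantile(mus, 1.0 - alpha, axis=0)])


def _chol_ok(V: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(V)
        return True
    except np.linalg.LinAlgError:
        return False


def probabilistic_index(fit: FittedMTRAM, x1, x2, u=None,
                        params: ParameterVector | None = None) -> float:
    """P(Y1 > Y2) for independent draws from the marginal distributions at
    covariates x1 and x2 (same design row u).

    On the latent scale both margins are the link distribution F shifted by
    their scaled linear predictors, so the index is the one-dimensional
    integral int F(v - c) f(v) dv with c = (x2 - x1)'beta / scale.
    """
    pv = fit.params if params is None else params
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    u_arr = np.ones(fit.design.R) if u is None else np.atleast_1d(np.asarray(u, float))
    s = marginal_scale(u_arr, pv.gamma)
    c = float((x2 - x1) @ pv.beta) / s
    link = fit.link

    def integrand(v):
        return link.cdf(v - c) * link.pdf(v)

    val, err = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    if err > 1e-6:
        raise RuntimeError(f"probabilistic-index quadrature error {err:g}")
    return float(min(max(val, 0.0), 1.0))
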