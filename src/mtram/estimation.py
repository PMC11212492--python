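"""Constrained maximum-likelihood estimation of (theta, beta, gamma).

The optimizer works on an unconstrained-plus-box chart that encodes the
linear constraints exactly:

* Bernstein / ordinal coefficients are re-expressed as a level plus
  nonnegative first differences (theta = cumsum(xi), xi[1:] >= 0), which is
  precisely C theta >= 0 for the first-difference constraint matrix;
* the slope coefficient of the linear / log-linear bases is bounded below
  by a tiny positive number;
* diagonal entries of the Cholesky factor Lambda(gamma) are bounded below
  by 0, so independence (gamma_1 = 0) is attainable on the boundary.

On this chart bound-constrained L-BFGS-B (default) or SLSQP maximizes the
summed cluster log-likelihood with analytic scores.  The observed-information
covariance is the inverse of the numerically differentiated negative Hessian
(central differences of the analytic score) in the original coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .basis import BasisSpec, default_support
from .covariance import RandomEffectDesign, n_gamma
from .data import ClusteredData
from .likelihood import ParameterVector, TransformationLikelihood
from .links import get_link

__all__ = ["ModelSpec", "FittedMTRAM", "initial_values", "fit_mtram", "vcov_observed"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of a marginal transformation model."""

    link: str = "logit"
    basis: BasisSpec | None = None          # inferred from the data when None
    basis_kind: str = "bernstein"
    order: int = 6
    design: str = "intercept"               # 'intercept' or 'intercept_slope'
    likelihood_kind: str | None = None      # inferred: exact -> continuous

    def resolve_basis(self, data: ClusteredData) -> BasisSpec:
        if self.basis is not None:
            return self.basis
        if self.basis_kind == "bernstein":
            return BasisSpec("bernstein", self.order,
                             default_support(data.lower, data.upper))
        if self.basis_kind == "ordinal_steps":
            hi = data.upper[np.isfinite(data.upper)]
            n_levels = int(np.nanmax(hi)) + 1 if hi.size else 2
            return BasisSpec("ordinal_steps", n_levels=n_levels)
        if self.basis_kind in ("linear", "loglinear"):
            return BasisSpec(self.basis_kind,
                             support=default_support(data.lower, data.upper))
        return BasisSpec(self.basis_kind)


@dataclass
class FittedMTRAM:
    """Maximum-likelihood fit: estimates, log-likelihood, vcov, diagnostics."""

    params: ParameterVector
    loglik: float
    spec: ModelSpec
    basis: BasisSpec
    design: RandomEffectDesign
    engine: TransformationLikelihood
    convergence: dict[str, Any] = field(default_factory=dict)
    _vcov: np.ndarray | None = None

    @property
    def n_theta(self) -> int:
        return self.params.theta.shape[0]

    @property
    def vcov(self) -> np.ndarray:
        if self._vcov is None:
            self._vcov = vcov_observed(self)
        return self._vcov

    @property
    def link(self):
        return get_link(self.spec.link)

    def summary(self) -> str:
        pv = self.params
        lines = [
            "Marginal transformation model fit",
            f"  link: {self.spec.link} ({self.link.scale_name})",
            f"  basis: {self.basis.kind} (P={self.basis.n_param})",
            f"  random effects: {self.design.kind}",
            f"  log-likelihood: {self.loglik:.4f}",
            f"  converged: {self.convergence.get('success')}",
            "  theta: " + np.array2string(pv.theta, precision=4),
            "  beta:  " + np.array2string(pv.beta, precision=4),
            "  gamma: " + np.array2string(pv.gamma, precision=4),
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# chart between free optimizer coordinates xi and model coordinates
# ----------------------------------------------------------------------
class _Chart:
    """theta-blockwise cumulative-sum reparameterization plus box bounds."""

    def __init__(self, engine: TransformationLikelihood):
        self.engine = engine
        basis, S = engine.basis, engine.S
        P, Q, M, R = engine.P, engine.Q, engine.M, engine.design.R
        self.cumsum_blocks = basis.kind in ("bernstein", "ordinal_steps")
        bounds: list[tuple[float | None, float | None]] = []
        for _ in range(S):
            if self.cumsum_blocks:
                bounds += [(None, None)] + [(0.0, None)] * (P - 1)
            elif basis.kind == "linear":
                bounds += [(1e-10, None), (None, None)]
            elif basis.kind == "loglinear":
                bounds += [(None, None), (1e-10, None)]
            else:
                bounds += [(None, None)] * P
        bounds += [(None, None)] * Q
        diag = {0} if R == 1 else {0, 2}
        bounds += [(0.0, None) if k in diag else (None, None) for k in range(M)]
        self.bounds = bounds
        self.S, self.P, self.Q, self.M = S, P, Q, M

    def to_model(self, xi: np.ndarray) -> np.ndarray:
        x = np.asarray(xi, dtype=float).copy()
        if self.cumsum_blocks:
            for s in range(self.S):
                blk = slice(s * self.P, (s + 1) * self.P)
                x[blk] = np.cumsum(x[blk])
        return x

    def to_chart(self, params: np.ndarray) -> np.ndarray:
        x = np.asarray(params, dtype=float).copy()
        if self.cumsum_blocks:
            for s in range(self.S):
                blk = slice(s * self.P, (s + 1) * self.P)
                x[blk] = np.concatenate([[x[blk][0]], np.diff(x[blk])])
        return x

    def grad_to_chart(self, grad: np.ndarray) -> np.ndarray:
        g = np.asarray(grad, dtype=float).copy()
        if self.cumsum_blocks:
            for s in range(self.S):
                blk = slice(s * self.P, (s + 1) * self.P)
                g[blk] = np.cumsum(g[blk][::-1])[::-1]
        return g


# ----------------------------------------------------------------------
def initial_values(data: ClusteredData, spec: ModelSpec, *,
                   independence_iter: int = 60) -> ParameterVector:
    """Starting point: (theta, beta) from an independence fit (gamma = 0
    decouples the clusters), then gamma diagonal entries at 0.1."""
    basis = spec.resolve_basis(data)
    design = RandomEffectDesign(spec.design)
    link = get_link(spec.link)
    Q = data.n_covariates
    S = data.n_strata
    M = n_gamma(design.R)

    theta0 = _moment_theta(data, basis, link)
    theta0 = np.tile(theta0, S)
    beta0 = np.zeros(Q)
    gamma0 = np.zeros(M)

    engine = TransformationLikelihood(data, link, basis, design,
                                      n_nodes=5)  # gamma=0: nodes are irrelevant
    chart = _Chart(engine)
    nfree = engine.n_theta + Q

    def negfun(xi_free):
        xi = np.concatenate([xi_free, gamma0])
        x = chart.to_model(xi)
        ll = engine.loglik(x)
        if not np.isfinite(ll):
            return 1e12, np.zeros(nfree)
        g = engine.score(x)
        return -ll, -chart.grad_to_chart(g)[:nfree]

    xi0 = chart.to_chart(np.concatenate([theta0, beta0, gamma0]))[:nfree]
    xi0 = _clip_to_bounds(xi0, chart.bounds[:nfree])
    res = optimize.minimize(negfun, xi0, jac=True, method="L-BFGS-B",
                            bounds=chart.bounds[:nfree],
                            options={"maxiter": independence_iter})
    xfit = chart.to_model(np.concatenate([res.x, gamma0]))
    pv = ParameterVector(xfit[:engine.n_theta], xfit[engine.n_theta:engine.n_theta + Q],
                         np.full(M, 0.1) * _diag_mask(design.R))
    ll = engine.loglik(pv)
    if not np.isfinite(ll):
        raise RuntimeError("independence starting values give non-finite log-likelihood")
    return pv


def _diag_mask(R: int) -> np.ndarray:
    if R == 1:
        return np.ones(1)
    return np.array([1.0, 0.0, 1.0])


def _clip_to_bounds(x: np.ndarray, bounds) -> np.ndarray:
    out = x.copy()
    for k, (lo, hi) in enumerate(bounds):
        if lo is not None:
            out[k] = max(out[k], lo if lo > 0 else lo)
        if hi is not None:
            out[k] = min(out[k], hi)
    # strictly positive differences keep h increasing at the start
    return out


def _moment_theta(data: ClusteredData, basis: BasisSpec, link) -> np.ndarray:
    """Crude monotone start for the transformation coefficients."""
    if basis.kind == "linear":
        y = data.y
        s = max(float(np.std(y)), 1e-8)
        return np.array([1.0 / s, float(np.mean(y)) / s])
    if basis.kind == "loglinear":
        ly = np.log(np.clip(data.lower[np.isfinite(data.lower)], 1e-12, None))
        s = max(float(np.std(ly)), 1e-8)
        return np.array([-float(np.mean(ly)) / s, 1.0 / s])
    if basis.kind == "binary_intercept":
        # alpha from the link quantile of the marginal frequency P(Y = 0)
        p0 = float(np.mean(np.isfinite(data.upper)))  # rows (-inf, alpha]
        p0 = min(max(p0, 1e-3), 1 - 1e-3)
        return np.array([float(link.quantile(np.array(p0)))])
    if basis.kind == "ordinal_steps":
        Km1 = basis.n_param
        ps = (np.arange(1, Km1 + 1)) / (Km1 + 1)
        return link.quantile(ps)
    # bernstein: match h(y) ~ F^{-1}(ECDF(y)) at the basis grid
    if data.all_exact:
        y = data.y
    else:
        fin = np.concatenate([data.lower[np.isfinite(data.lower)],
                              data.upper[np.isfinite(data.upper)]])
        y = fin
    lo, hi = basis.support
    grid = np.linspace(lo, hi, basis.n_param)
    ecdf = np.clip((np.searchsorted(np.sort(y), grid, side="right")) / (y.size + 1),
                   1e-3, 1 - 1e-3)
    targets = np.asarray(link.quantile(ecdf), dtype=float)
    # enforce strictly increasing coefficients
    diffs = np.maximum(np.diff(targets), 1e-3)
    return np.concatenate([[targets[0]], targets[0] + np.cumsum(diffs)])


# ----------------------------------------------------------------------
def fit_mtram(data: ClusteredData, spec: ModelSpec, *, start: ParameterVector | None = None,
              method: str = "L-BFGS-B", n_nodes: int = 40, gtol: float = 1e-5,
              ftol: float = 1e-10, maxiter: int = 500,
              compute_vcov: bool = False) -> FittedMTRAM:
    """Maximize the summed cluster log-likelihood subject to C theta >= 0 and
    diag(Lambda) >= 0; gamma may land on the independence boundary."""
    basis = spec.resolve_basis(data)
    design = RandomEffectDesign(spec.design)
    engine = TransformationLikelihood(data, spec.link, basis, design, n_nodes=n_nodes)
    if start is None:
        start = initial_values(data, spec)
    chart = _Chart(engine)

    def negfun(xi):
        x = chart.to_model(xi)
        ll = engine.loglik(x)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(xi)
        g = engine.score(x)
        return -ll, -chart.grad_to_chart(g)

    xi0 = _clip_to_bounds(chart.to_chart(start.flat), chart.bounds)
    if method == "SLSQP":
        res = optimize.minimize(negfun, xi0, jac=True, method="SLSQP",
                                bounds=chart.bounds,
                                options={"maxiter": maxiter, "ftol": ftol})
    else:
        res = optimize.minimize(negfun, xi0, jac=True, method="L-BFGS-B",
                                bounds=chart.bounds,
                                options={"maxiter": maxiter, "gtol": gtol,
                                         "ftol": ftol})
    xhat = chart.to_model(res.x)
    pv = ParameterVector.from_flat(xhat, engine.n_theta, engine.Q)
    ll = engine.loglik(pv)
    active = [k for k, (lo, _) in enumerate(chart.bounds)
              if lo is not None and res.x[k] <= lo + 1e-9]
    if not res.success:
        logger.warning("optimizer did not report convergence: %s", res.message)
    conv = {
        "success": bool(res.success),
        "message": str(res.message),
        "n_iter": int(res.get("nit", -1)),
        "grad_norm": float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        "active_constraints": active,
        "boundary_gamma": bool(np.any(pv.gamma[_diag_idx(design.R)] <= 1e-8)),
    }
    fit = FittedMTRAM(params=pv, loglik=float(ll), spec=spec, basis=basis,
                      design=design, engine=engine, convergence=conv)
    if compute_vcov:
        fit._vcov = vcov_observed(fit)
    return fit


def _diag_idx(R: int) -> np.ndarray:
    return np.array([0]) if R == 1 else np.array([0, 2])


# ----------------------------------------------------------------------
def vcov_observed(fit: FittedMTRAM, step: float = 1e-5) -> np.ndarray:
    """Inverse of the numerically differentiated negative Hessian of the total
    log-likelihood at the optimum (central differences of the analytic score).

    Diagonal gamma entries sitting on the nonnegativity boundary are
    differentiated one-sided.  A non-invertible Hessian falls back to the
    Moore-Penrose pseudo-inverse with an eigenvalue report in the log.
    """
    engine = fit.engine
    x0 = fit.params.flat
    n = x0.shape[0]
    H = np.zeros((n, n))
    lo_bound = np.full(n, -np.inf)
    gdiag = engine.n_theta + engine.Q + _diag_idx(engine.design.R)
    lo_bound[gdiag] = 0.0

    for k in range(n):
        hstep = step * max(1.0, abs(x0[k]))
        xp, xm = x0.copy(), x0.copy()
        xp[k] += hstep
        xm[k] -= hstep
        if xm[k] < lo_bound[k]:
            x2 = x0.copy()
            x2[k] += 2 * hstep
            H[:, k] = (-3 * engine.score(x0) + 4 * engine.score(xp)
                       - engine.score(x2)) / (2 * hstep)
        else:
            H[:, k] = (engine.score(xp) - engine.score(xm)) / (2 * hstep)
    H = 0.5 * (H + H.T)
    neg_H = -H
    try:
        np.linalg.cholesky(neg_H + 1e-12 * np.eye(n))
        V = np.linalg.inv(neg_H)
    except np.linalg.LinAlgError:
        # project onto the positive part: invert only the directions with
        # positive curvature, leaving flat/indefinite ones at variance 0
        w, Q = np.linalg.eigh(neg_H)
        logger.warning("observed information not positive definite "
                       "(eigenvalues %s); using its positive part", w)
        tol = 1e-10 * max(1.0, np.max(np.abs(w)))
        w_inv = np.where(w > tol, 1.0 / np.maximum(w, tol), 0.0)
        V = (Q * w_inv) @ Q.T
    return 0.5 * (V + V.T)
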