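"""Likelihoods of the Gaussian-copula transformation model.

The joint model for a cluster of size Ni states that the latent vector

    Z_i = D_i Phi^{-1}( F( D_i^{-1} [ A(y) theta - X_i beta ] ) )

is N(0, Sigma_i(gamma)) with Sigma_i = U_i L L' U_i' + I and D_i the square
roots of diag(Sigma_i).  Two likelihoods are implemented:

* continuous responses: the approximate log-density

      -1/2 log|Sigma_i| - 1/2 z'(Sigma_i^{-1} - D_i^{-2})z
      + sum_j log f(m_j) + sum_j log a'(y_j)'theta,

  with m = D^{-1}(A(y)theta - X beta), evaluated via the Woodbury identity
  so only an R x R system is ever solved;

* censored / discrete responses: the exact rectangle probability
  log P(z(lower) < Z_i <= z(upper)).  Exploiting Z_i = U_i L s + eps with
  s ~ N(0, I_R), the Ni-dimensional normal integral reduces to an
  R-dimensional one, evaluated by deterministic Gauss-Hermite quadrature
  (tensorized for R=2).

Scores with respect to (theta, beta) are analytic (for the censored
likelihood, by differentiating the quadrature approximation exactly);
derivatives with respect to gamma use central finite differences on a
cheap cached path.  All per-observation quantities are vectorized across
the whole data set; cluster reductions use ``np.add.reduceat``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, logsumexp, ndtri, roots_hermitenorm

from .basis import BasisSpec, basis_deriv_matrix, basis_matrix
from .covariance import RandomEffectDesign, cholesky_factor, n_gamma
from .data import ClusteredData
from .links import LinkFamily, get_link, _PCLIP, _log1mexp

logger = logging.getLogger(__name__)

__all__ = ["ParameterVector", "TransformationLikelihood", "latent_transform",
           "mvn_rectangle", "loglik_continuous", "loglik_censored",
           "score_continuous"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_GAMMA_FD_STEP = 1e-5


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ParameterVector:
    """(theta, beta, gamma): transformation coefficients (concatenated over
    strata), fixed effects, and covariance parameters."""

    theta: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "beta", np.asarray(self.beta, float).reshape(-1))
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, float)))

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate([self.theta, self.beta, self.gamma])

    @classmethod
    def from_flat(cls, x: np.ndarray, n_theta: int, n_beta: int) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        return cls(x[:n_theta], x[n_theta:n_theta + n_beta], x[n_theta + n_beta:])


# ----------------------------------------------------------------------
# quadrature and stable normal rectangles
# ----------------------------------------------------------------------
def gauss_hermite_nodes(R: int, n_nodes: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Nodes (K, R) and log-weights (K,) for E[g(s)], s ~ N(0, I_R)."""
    x, w = roots_hermitenorm(n_nodes)
    logw = np.log(w) - 0.5 * np.log(2.0 * np.pi)
    if R == 1:
        return x[:, None], logw
    if R == 2:
        xx, yy = np.meshgrid(x, x, indexing="ij")
        nodes = np.column_stack([xx.ravel(), yy.ravel()])
        lw = (logw[:, None] + logw[None, :]).ravel()
        return nodes, lw
    raise ValueError("random-effect dimension R > 2 is not supported")


def log_normal_rectangle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) elementwise, a <= b, stable in both tails."""
    a, b = np.broadcast_arrays(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    out = np.full(a.shape, -np.inf)
    lo_inf = np.isneginf(a)
    hi_inf = np.isposinf(b)
    out[lo_inf & hi_inf] = 0.0
    only_lo = lo_inf & ~hi_inf
    out[only_lo] = log_ndtr(b[only_lo])
    only_hi = hi_inf & ~lo_inf
    out[only_hi] = log_ndtr(-a[only_hi])
    fin = ~(lo_inf | hi_inf)
    if np.any(fin):
        af, bf = a[fin], b[fin]
        # difference in the shorter tail: use the survival side when both > 0
        use_sf = (af + bf) > 0.0
        hi_l = np.where(use_sf, log_ndtr(-af), log_ndtr(bf))
        lo_l = np.where(use_sf, log_ndtr(-bf), log_ndtr(af))
        with np.errstate(invalid="ignore"):
            vals = hi_l + _log1mexp(np.minimum(lo_l - hi_l, 0.0))
        vals = np.where(af == bf, -np.inf, vals)
        out[fin] = vals
    return out


# ----------------------------------------------------------------------
# engine
# ----------------------------------------------------------------------
class TransformationLikelihood:
    """Evaluates the model log-likelihood and scores on a fixed data set.

    Parameters
    ----------
    data : ClusteredData
    link : LinkFamily or str
    basis : BasisSpec
    design : RandomEffectDesign
    n_nodes : int
        Gauss-Hermite nodes per latent dimension for censored likelihoods.
    """

    def __init__(self, data: ClusteredData, link: LinkFamily | str,
                 basis: BasisSpec, design: RandomEffectDesign,
                 n_nodes: int = 40):
        self.data = data
        self.link = get_link(link) if isinstance(link, str) else link
        self.basis = basis
        self.design = design
        self.n_nodes = n_nodes
        self.S = data.n_strata
        self.P = basis.n_param
        self.Q = data.n_covariates
        self.M = n_gamma(design.R)
        self.n_theta = self.S * self.P
        self.n_param = self.n_theta + self.Q + self.M
        self.kind = "continuous" if data.all_exact else "censored"
        data.validate_kind(self.kind)
        self._strata = data.strata if data.strata is not None else None
        self._prepare()

    # -- precomputation ------------------------------------------------
    def _prepare(self):
        d = self.data
        if self.design.kind == "intercept":
            self._U = np.ones((d.n_obs, 1))
        else:
            if d.time is None:
                raise ValueError("intercept_slope design needs a time column")
            self._U = np.column_stack([np.ones(d.n_obs), d.time])
        if self.kind == "continuous":
            y = d.y
            self._A = basis_matrix(self.basis, y)
            self._Ad = basis_deriv_matrix(self.basis, y)
        else:
            lo, up = d.lower, d.upper
            self._fin_lo = np.isfinite(lo)
            self._fin_up = np.isfinite(up)
            self._A_lo = np.zeros((d.n_obs, self.P))
            self._A_up = np.zeros((d.n_obs, self.P))
            if np.any(self._fin_lo):
                self._A_lo[self._fin_lo] = basis_matrix(self.basis, lo[self._fin_lo])
            if np.any(self._fin_up):
                self._A_up[self._fin_up] = basis_matrix(self.basis, up[self._fin_up])
            self._nodes, self._logw = gauss_hermite_nodes(self.design.R, self.n_nodes)

    def _h(self, A: np.ndarray, theta: np.ndarray) -> np.ndarray:
        if self.S == 1:
            return A @ theta
        tm = theta.reshape(self.S, self.P)
        return np.einsum("np,np->n", A, tm[self._strata])

    def _accumulate_theta(self, A: np.ndarray, w: np.ndarray) -> np.ndarray:
        """sum_j w_j a(y_j) accumulated per stratum, flattened."""
        if self.S == 1:
            return A.T @ w
        out = np.zeros((self.S, self.P))
        np.add.at(out, self._strata, A * w[:, None])
        return out.ravel()

    def _scales(self, gamma: np.ndarray) -> np.ndarray:
        """Per-observation D_jj = sqrt(u_j' L L' u_j + 1)."""
        L = cholesky_factor(gamma, self.design.R)
        return np.sqrt(np.sum((self._U @ L) ** 2, axis=1) + 1.0)

    def _params(self, params) -> ParameterVector:
        if isinstance(params, ParameterVector):
            return params
        return ParameterVector.from_flat(np.asarray(params, float), self.n_theta, self.Q)

    # -- latent transform ---------------------------------------------
    def latent_values(self, eta: np.ndarray, dvec: np.ndarray) -> np.ndarray:
        """z = D Phi^{-1}(F(eta / D)) elementwise; eta may contain +-inf."""
        if self.link.name == "probit":
            return eta
        with np.errstate(invalid="ignore"):
            m = eta / dvec
        p = self.link.cdf(m)
        q = ndtri(np.clip(p, _PCLIP, 1.0 - _PCLIP))
        q = np.where(np.isneginf(eta), -np.inf, q)
        q = np.where(np.isposinf(eta), np.inf, q)
        return dvec * q

    # -- continuous likelihood ----------------------------------------
    def loglik(self, params) -> float:
        pv = self._params(params)
        if self.kind == "continuous":
            return self._cont(pv)[0]
        return self._cens(pv)[0]

    def cluster_loglik(self, params) -> np.ndarray:
        pv = self._params(params)
        if self.kind == "continuous":
            return self._cont(pv, per_cluster=True)[1]
        return self._cens(pv, per_cluster=True)[1]

    def score(self, params) -> np.ndarray:
        """Gradient of the total log-likelihood w.r.t. (theta, beta, gamma)."""
        pv = self._params(params)
        if self.kind == "continuous":
            return self._cont_score(pv)
        return self._cens_score(pv)

    # internal: continuous pieces given eta = h - X beta
    def _cont_core(self, eta: np.ndarray, gamma: np.ndarray,
                   want_grad: bool = False, per_cluster: bool = False):
        d = self.data
        dvec = self._scales(gamma)
        m = eta / dvec
        if self.link.name == "probit":
            q = m
            logf = -0.5 * m * m - _LOG_SQRT_2PI
        else:
            p = np.clip(self.link.cdf(m), _PCLIP, 1.0 - _PCLIP)
            q = ndtri(p)
            logf = self.link.logpdf(m)
        z = dvec * q

        R = self.design.R
        L = cholesky_factor(gamma, R)
        cl_ll = np.zeros(d.n_clusters)
        Minvz = np.empty_like(z)  # (Sigma^{-1} - D^{-2}) z
        logf_cl = np.add.reduceat(logf, d.starts)
        if R == 1 and self.design.kind == "intercept":
            c = float(L[0, 0]) ** 2
            zsum = np.add.reduceat(z, d.starts)
            zsq = np.add.reduceat(z * z, d.starts)
            qsq = np.add.reduceat(q * q, d.starts)
            denom = 1.0 + d.sizes * c
            cl_ll = (-0.5 * np.log(denom)
                     - 0.5 * (zsq - (c / denom) * zsum ** 2 - qsq)
                     + logf_cl)
            if want_grad:
                Minvz = z - np.repeat((c / denom) * zsum, d.sizes) - z / dvec ** 2
        else:
            for i in range(d.n_clusters):
                s, ni = d.starts[i], d.sizes[i]
                sl = slice(s, s + ni)
                G = self._U[sl] @ L                      # (ni, R)
                K = np.eye(R) + G.T @ G
                zi = z[sl]
                w = G.T @ zi
                Kinv_w = np.linalg.solve(K, w)
                sign, logdet = np.linalg.slogdet(K)
                zSz = zi @ zi - w @ Kinv_w
                cl_ll[i] = -0.5 * logdet - 0.5 * (zSz - q[sl] @ q[sl]) + logf_cl[i]
                if want_grad:
                    Minvz[sl] = zi - G @ Kinv_w - zi / dvec[sl] ** 2
        per = cl_ll if per_cluster else None
        total = float(np.sum(cl_ll))
        if not want_grad:
            return total, per
        # d ll / d m_j  (chain through z_j = d_j * Phi^{-1}(F(m_j)))
        if self.link.name == "probit":
            ratio = np.ones_like(m)
            dlogf = -m
        else:
            phi_q = np.exp(-0.5 * q * q) / np.sqrt(2.0 * np.pi)
            ratio = self.link.pdf(m) / phi_q
            dlogf = self.link.dlogpdf(m)
        dll_dm = -Minvz * dvec * ratio + dlogf
        dll_deta = dll_dm / dvec
        return total, per, dll_deta

    def _cont(self, pv: ParameterVector, per_cluster: bool = False):
        h = self._h(self._A, pv.theta)
        hp = self._h(self._Ad, pv.theta)
        if np.any(hp <= 0.0):
            bad = np.full(self.data.n_clusters, -np.inf) if per_cluster else None
            return -np.inf, bad
        eta = h - (self.data.X @ pv.beta if self.Q else 0.0)
        total, per = self._cont_core(eta, pv.gamma, per_cluster=per_cluster)[:2]
        jac = np.log(hp)
        total += float(np.sum(jac))
        if per_cluster:
            per = per + np.add.reduceat(jac, self.data.starts)
        return total, per

    def _cont_score(self, pv: ParameterVector) -> np.ndarray:
        h = self._h(self._A, pv.theta)
        hp = self._h(self._Ad, pv.theta)
        if np.any(hp <= 0.0):
            raise FloatingPointError("a'(y)'theta <= 0: monotonicity constraint violated")
        eta = h - (self.data.X @ pv.beta if self.Q else 0.0)
        _, _, dll_deta = self._cont_core(eta, pv.gamma, want_grad=True)
        g_theta = self._accumulate_theta(self._A, dll_deta) \
            + self._accumulate_theta(self._Ad, 1.0 / hp)
        g_beta = -(self.data.X.T @ dll_deta) if self.Q else np.zeros(0)
        g_gamma = self._fd_gamma(lambda g: self._cont_core(eta, g)[0], pv.gamma)
        return np.concatenate([g_theta, g_beta, g_gamma])

    # -- censored likelihood ------------------------------------------
    def _cens_core(self, eta_lo: np.ndarray, eta_up: np.ndarray, gamma: np.ndarray,
                   want_grad: bool = False, per_cluster: bool = False):
        d = self.data
        dvec = self._scales(gamma)
        z_lo = self.latent_values(eta_lo, dvec)
        z_up = self.latent_values(eta_up, dvec)
        L = cholesky_factor(gamma, self.design.R)
        if self.design.R == 1 and self.design.kind == "intercept":
            out = _agq_rect_r1(z_lo, z_up, float(L[0, 0]), d.starts, d.sizes,
                               self._nodes[:, 0], self._logw, want_grad)
        else:
            out = _fixed_rect(z_lo, z_up, self._U @ L, d.starts, d.sizes,
                              self._nodes, self._logw, want_grad)
        cl_ll = out[0]
        total = float(np.sum(cl_ll))
        if not want_grad:
            return total, (cl_ll if per_cluster else None)
        dll_dzlo, dll_dzup = out[1], out[2]
        return total, (cl_ll if per_cluster else None), dll_dzlo, dll_dzup, dvec

    def _etas(self, pv: ParameterVector) -> tuple[np.ndarray, np.ndarray]:
        d = self.data
        xb = d.X @ pv.beta if self.Q else np.zeros(d.n_obs)
        eta_lo = np.where(self._fin_lo, self._h(self._A_lo, pv.theta) - xb, -np.inf)
        eta_up = np.where(self._fin_up, self._h(self._A_up, pv.theta) - xb, np.inf)
        return eta_lo, eta_up

    def _cens(self, pv: ParameterVector, per_cluster: bool = False):
        eta_lo, eta_up = self._etas(pv)
        total, per = self._cens_core(eta_lo, eta_up, pv.gamma,
                                     per_cluster=True)[:2]
        if not np.isfinite(total):
            bad = np.nonzero(~np.isfinite(per))[0]
            labels = np.asarray(self.data.cluster_labels)[bad[:5]]
            logger.warning("censored likelihood underflow in %d cluster(s), "
                           "e.g. ids %s", bad.size, labels.tolist())
        return total, (per if per_cluster else None)

    def _cens_score(self, pv: ParameterVector) -> np.ndarray:
        eta_lo, eta_up = self._etas(pv)
        total, _, dll_dzlo, dll_dzup, dvec = self._cens_core(
            eta_lo, eta_up, pv.gamma, want_grad=True)
        if not np.isfinite(total):
            raise FloatingPointError("censored likelihood underflow; cannot differentiate")
        # chain rule zeta = D Phi^{-1}(F(eta/D)): dzeta/deta = f(m)/phi(q)
        r_lo = self._bound_ratio(eta_lo, dvec)
        r_up = self._bound_ratio(eta_up, dvec)
        w_lo = np.where(self._fin_lo, dll_dzlo * r_lo, 0.0)
        w_up = np.where(self._fin_up, dll_dzup * r_up, 0.0)
        g_theta = self._accumulate_theta(self._A_lo, w_lo) \
            + self._accumulate_theta(self._A_up, w_up)
        g_beta = -(self.data.X.T @ (w_lo + w_up)) if self.Q else np.zeros(0)
        g_gamma = self._fd_gamma(
            lambda g: self._cens_core(eta_lo, eta_up, g)[0], pv.gamma)
        return np.concatenate([g_theta, g_beta, g_gamma])

    def _bound_ratio(self, eta: np.ndarray, dvec: np.ndarray) -> np.ndarray:
        if self.link.name == "probit":
            return np.ones_like(eta)
        with np.errstate(invalid="ignore"):
            m = np.where(np.isfinite(eta), eta / dvec, 0.0)
        p = np.clip(self.link.cdf(m), _PCLIP, 1.0 - _PCLIP)
        q = ndtri(p)
        phi_q = np.exp(-0.5 * q * q) / np.sqrt(2.0 * np.pi)
        return self.link.pdf(m) / phi_q

    # -- gamma finite differences -------------------------------------
    def _fd_gamma(self, fun, gamma: np.ndarray) -> np.ndarray:
        g = np.asarray(gamma, dtype=float)
        out = np.zeros_like(g)
        for k in range(g.shape[0]):
            hstep = _GAMMA_FD_STEP * max(1.0, abs(g[k]))
            gp, gm = g.copy(), g.copy()
            gp[k] += hstep
            gm[k] -= hstep
            if _is_diag_entry(k, self.design.R) and gm[k] < 0.0:
                # one-sided at the nonnegativity boundary
                g2 = g.copy()
                g2[k] += 2 * hstep
                out[k] = (-3 * fun(g) + 4 * fun(gp) - fun(g2)) / (2 * hstep)
            else:
                out[k] = (fun(gp) - fun(gm)) / (2 * hstep)
        return out


def _is_diag_entry(k: int, R: int) -> bool:
    """Is flat row-wise lower-triangular index k a diagonal entry?"""
    diag = []
    idx = 0
    for r in range(R):
        idx += r + 1
        diag.append(idx - 1)
    return k in diag


# ----------------------------------------------------------------------
# quadrature kernels for the rectangle probabilities
# ----------------------------------------------------------------------
def _phi(x):
    return np.exp(-0.5 * np.square(x)) / np.sqrt(2.0 * np.pi)


def _masked_phi(x):
    """phi(x) with 0 at infinite arguments."""
    with np.errstate(over="ignore", invalid="ignore"):
        return np.where(np.isfinite(x), _phi(np.where(np.isfinite(x), x, 0.0)), 0.0)


def _agq_rect_r1(z_lo, z_up, lam, starts, sizes, x_nodes, logw, want_grad,
                 newton_iter: int = 12):
    """Adaptive Gauss-Hermite reduction of the compound-symmetry rectangle.

    P_i = int phi(s) prod_j [Phi(zu_j - lam s) - Phi(zl_j - lam s)] ds is
    computed after recentering/rescaling the rule at the mode and curvature
    of the log-integrand (found by a vectorized Newton iteration), which
    keeps the rule accurate for any lam (the fixed rule degrades once the
    integrand becomes much narrower than the weight function).
    """
    N = starts.shape[0]
    rep = np.repeat(np.arange(N), sizes)
    s = np.zeros(N)
    if lam != 0.0:
        for _ in range(newton_iter):
            a = z_lo - lam * s[rep]
            b = z_up - lam * s[rep]
            logdelta = log_normal_rectangle(a, b)
            with np.errstate(over="ignore", invalid="ignore"):
                ra = np.where(np.isfinite(a),
                              np.exp(np.minimum(-0.5 * np.square(np.nan_to_num(a))
                                                - _LOG_SQRT_2PI - logdelta, 45.0)), 0.0)
                rb = np.where(np.isfinite(b),
                              np.exp(np.minimum(-0.5 * np.square(np.nan_to_num(b))
                                                - _LOG_SQRT_2PI - logdelta, 45.0)), 0.0)
            g1 = -s + lam * np.add.reduceat(ra - rb, starts)
            with np.errstate(invalid="ignore"):
                t = (np.where(np.isfinite(a), np.nan_to_num(a * ra), 0.0)
                     - np.where(np.isfinite(b), np.nan_to_num(b * rb), 0.0)
                     - (ra - rb) ** 2)
            g2 = -1.0 + lam ** 2 * np.add.reduceat(t, starts)
            g2 = np.minimum(g2, -1e-8)
            step = np.clip(g1 / (-g2), -2.0, 2.0)
            s = s + step
            if np.max(np.abs(step)) < 1e-10:
                break
        sigma = 1.0 / np.sqrt(-g2)
    else:
        sigma = np.ones(N)
    # transformed nodes per cluster
    s_nodes = s[:, None] + sigma[:, None] * x_nodes[None, :]       # (N, K)
    g_obs = lam * s_nodes[rep]                                     # (n, K)
    a = z_lo[:, None] - g_obs
    b = z_up[:, None] - g_obs
    logdelta = log_normal_rectangle(a, b)
    S_ik = np.add.reduceat(logdelta, starts, axis=0) - 0.5 * s_nodes ** 2
    c_ik = S_ik + logw[None, :] + 0.5 * x_nodes[None, :] ** 2
    lse = logsumexp(c_ik, axis=1)
    cl_ll = np.log(sigma) + lse
    if not want_grad:
        return (cl_ll,)
    expo = np.minimum(c_ik[rep] - lse[rep][:, None] - logdelta, 700.0)
    with np.errstate(over="ignore", invalid="ignore"):
        W = np.exp(expo)
    dll_dzup = np.einsum("nk,nk->n", W, _masked_phi(b))
    dll_dzlo = -np.einsum("nk,nk->n", W, _masked_phi(a))
    return cl_ll, dll_dzlo, dll_dzup


def _fixed_rect(z_lo, z_up, B, starts, sizes, nodes, logw, want_grad):
    """Fixed tensorized rule (used for the R=2 longitudinal design)."""
    N = starts.shape[0]
    g = B @ nodes.T                                    # (n, K)
    a = z_lo[:, None] - g
    b = z_up[:, None] - g
    logdelta = log_normal_rectangle(a, b)
    S_ik = np.add.reduceat(logdelta, starts, axis=0)
    cl_ll = logsumexp(S_ik + logw[None, :], axis=1)
    if not want_grad:
        return (cl_ll,)
    rep = np.repeat(np.arange(N), sizes)
    expo = np.minimum(S_ik[rep] - cl_ll[rep][:, None] + logw[None, :] - logdelta,
                      700.0)
    with np.errstate(over="ignore", invalid="ignore"):
        W = np.exp(expo)
    dll_dzup = np.einsum("nk,nk->n", W, _masked_phi(b))
    dll_dzlo = -np.einsum("nk,nk->n", W, _masked_phi(a))
    return cl_ll, dll_dzlo, dll_dzup


# ----------------------------------------------------------------------
# module-level operations (single-cluster / standalone contracts)
# ----------------------------------------------------------------------
def latent_transform(y, params: ParameterVector, *, link, basis: BasisSpec,
                     design: RandomEffectDesign, X=None, time=None) -> np.ndarray:
    """z(y | theta, beta, gamma) for one cluster; +-inf bounds map to +-inf."""
    link = get_link(link) if isinstance(link, str) else link
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = y.shape[0]
    X = np.zeros((n, params.beta.shape[0])) if X is None else np.atleast_2d(np.asarray(X, float))
    fin = np.isfinite(y)
    h = np.where(fin, 0.0, y)
    if np.any(fin):
        h[fin] = basis_matrix(basis, y[fin]) @ params.theta
    eta = np.where(fin, h - (X @ params.beta if params.beta.size else 0.0), h)
    U = design.U(n, time)
    L = cholesky_factor(params.gamma, design.R)
    dvec = np.sqrt(np.sum((U @ L) ** 2, axis=1) + 1.0)
    if link.name == "probit":
        return eta
    with np.errstate(invalid="ignore"):
        m = eta / dvec
    p = np.clip(link.cdf(m), _PCLIP, 1.0 - _PCLIP)
    q = ndtri(p)
    q = np.where(np.isneginf(eta), -np.inf, q)
    q = np.where(np.isposinf(eta), np.inf, q)
    return dvec * q


def mvn_rectangle(lower, upper, design: RandomEffectDesign, gamma,
                  time=None, n_nodes: int = 40, check: bool = False) -> float:
    """P(lower < Z <= upper) for Z ~ N(0, Sigma(gamma)) via the R-dimensional
    Gauss-Hermite reduction; with ``check=True`` a doubled rule must agree to
    1e-8 or a RuntimeError is raised."""
    lower = np.atleast_1d(np.asarray(lower, dtype=float))
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    if np.any(lower > upper):
        raise ValueError("lower > upper")
    n = lower.shape[0]
    U = design.U(n, time)
    L = cholesky_factor(gamma, design.R)

    starts = np.array([0])
    sizes = np.array([n])

    def _value(k_nodes: int) -> float:
        nodes, logw = gauss_hermite_nodes(design.R, k_nodes)
        if design.R == 1 and design.kind == "intercept":
            (cl_ll,) = _agq_rect_r1(lower, upper, float(L[0, 0]), starts, sizes,
                                    nodes[:, 0], logw, want_grad=False)
        else:
            (cl_ll,) = _fixed_rect(lower, upper, U @ L, starts, sizes,
                                   nodes, logw, want_grad=False)
        return float(np.exp(cl_ll[0]))

    val = _value(n_nodes)
    if check:
        val2 = _value(2 * n_nodes)
        if abs(val - val2) > 1e-8:
            raise RuntimeError(
                f"quadrature not converged: {val} vs {val2} at doubled rule")
        val = val2
    return min(max(val, 0.0), 1.0)


def _single_cluster_engine(cluster: ClusteredData, link, basis, design,
                           **kw) -> TransformationLikelihood:
    return TransformationLikelihood(cluster, link, basis, design, **kw)


def loglik_continuous(params: ParameterVector, cluster: ClusteredData, *,
                      link, basis, design) -> float:
    """Approximate log-density contribution of one (or more) exact clusters."""
    return _single_cluster_engine(cluster, link, basis, design).loglik(params)


def score_continuous(params: ParameterVector, cluster: ClusteredData, *,
                     link, basis, design) -> np.ndarray:
    return _single_cluster_engine(cluster, link, basis, design).score(params)


def loglik_censored(params: ParameterVector, cluster: ClusteredData, *,
                    link, basis, design, n_nodes: int = 40) -> float:
    """Exact log rectangle-probability contribution of censored clusters."""
    return _single_cluster_engine(cluster, link, basis, design,
                                  n_nodes=n_nodes).loglik(params)
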