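"""Parameterizations of the monotone transformation h(y) = a(y)' theta.

Supported bases:

* ``bernstein`` -- polynomial in Bernstein form of a given order on a
  bounded support; nondecreasing coefficient sequences give monotone h.
* ``linear`` -- a(y) = (y, -1), so h(y) = theta1*y - theta2; with
  theta = (1/sigma, alpha/sigma) this is the normal-model standardization
  (y - alpha)/sigma.
* ``loglinear`` -- a(y) = (1, log y), the Weibull / log-linear
  log-cumulative-hazard parameterization on (0, inf).
* ``binary_intercept`` -- a single cut point alpha for binary responses:
  h(0) = alpha, h(1) = +inf.
* ``ordinal_steps`` -- K-1 nondecreasing cut points for an ordered response
  with K levels (experimental; generalizes binary_intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import comb

__all__ = ["BasisSpec", "basis_row", "basis_matrix", "basis_deriv_row",
           "basis_deriv_matrix", "monotonicity_constraints"]

logger = logging.getLogger(__name__)

_CONTINUOUS = ("bernstein", "linear", "loglinear")
_DISCRETE = ("binary_intercept", "ordinal_steps")


@dataclass(frozen=True)
class BasisSpec:
    """Basis family, polynomial order and response support for h(y)=a(y)'theta."""

    kind: str
    order: int = 6
    support: tuple[float, float] = (0.0, 1.0)
    n_levels: int = 2  # ordinal_steps only

    def __post_init__(self):
        if self.kind not in _CONTINUOUS + _DISCRETE:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        lo, hi = self.support
        if self.kind == "bernstein":
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bernstein basis needs finite support lo < hi, got {self.support}")
            if self.order < 1:
                raise ValueError("bernstein order must be >= 1")
        if self.kind == "loglinear" and lo < 0:
            object.__setattr__(self, "support", (max(lo, 0.0), hi))
        if self.kind == "ordinal_steps" and self.n_levels < 2:
            raise ValueError("ordinal_steps needs at least 2 levels")

    @property
    def n_param(self) -> int:
        if self.kind == "bernstein":
            return self.order + 1
        if self.kind in ("linear", "loglinear"):
            return 2
        if self.kind == "binary_intercept":
            return 1
        return self.n_levels - 1

    @property
    def is_discrete(self) -> bool:
        return self.kind in _DISCRETE


def _bernstein_design(u: np.ndarray, order: int) -> np.ndarray:
    """Rows of Bernstein polynomials B_{p,order}(u), u in [0,1]."""
    p = np.arange(order + 1)
    binom = comb(order, p)
    u = u[:, None]
    # 0**0 := 1 at the endpoints
    with np.errstate(divide="ignore", invalid="ignore"):
        A = binom * np.power(u, p) * np.power(1.0 - u, order - p)
    return A


def _clamp(spec: BasisSpec, y: np.ndarray) -> np.ndarray:
    lo, hi = spec.support
    finite = np.isfinite(y)
    n_out = int(np.count_nonzero(finite & ((y < lo) | (y > hi))))
    if n_out:
        logger.debug("basis: clamped %d observations to support [%g, %g]", n_out, lo, hi)
    return np.clip(y, lo, hi)


def basis_matrix(spec: BasisSpec, y) -> np.ndarray:
    """Evaluate A(y): one basis row a(y_j)' per observation."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if spec.kind == "bernstein":
        lo, hi = spec.support
        u = (_clamp(spec, y) - lo) / (hi - lo)
        return _bernstein_design(u, spec.order)
    if spec.kind == "linear":
        return np.column_stack([y, -np.ones_like(y)])
    if spec.kind == "loglinear":
        if np.any(y <= 0):
            raise ValueError("loglinear basis requires positive responses")
        return np.column_stack([np.ones_like(y), np.log(y)])
    if spec.kind == "binary_intercept":
        # h(y) = alpha for every (finite) cut evaluation
        return np.ones((y.shape[0], 1))
    # ordinal_steps: y codes the cut index 1..K-1
    k = np.rint(y).astype(int)
    if np.any((k < 1) | (k > spec.n_levels - 1)):
        raise ValueError("ordinal cut index out of range")
    A = np.zeros((y.shape[0], spec.n_param))
    A[np.arange(y.shape[0]), k - 1] = 1.0
    return A


def basis_row(spec: BasisSpec, y: float) -> np.ndarray:
    """a(y) as a vector of length n_param."""
    return basis_matrix(spec, [y])[0]


def basis_deriv_matrix(spec: BasisSpec, y) -> np.ndarray:
    """Evaluate A'(y), the rows a'(y_j)'; continuous bases only."""
    if spec.is_discrete:
        raise ValueError(f"derivative undefined for discrete basis {spec.kind!r}")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if spec.kind == "bernstein":
        lo, hi = spec.support
        width = hi - lo
        u = (_clamp(spec, y) - lo) / width
        n = spec.order
        lower = _bernstein_design(u, n - 1)  # (m, n)
        D = np.zeros((y.shape[0], n + 1))
        # d/du B_{p,n} = n (B_{p-1,n-1} - B_{p,n-1})
        D[:, 1:] += n * lower
        D[:, :-1] -= n * lower
        return D / width
    if spec.kind == "linear":
        return np.column_stack([np.ones_like(y), np.zeros_like(y)])
    # loglinear
    if np.any(y <= 0):
        raise ValueError("loglinear basis requires positive responses")
    return np.column_stack([np.zeros_like(y), 1.0 / y])


def basis_deriv_row(spec: BasisSpec, y: float) -> np.ndarray:
    """a'(y) as a vector of length n_param."""
    return basis_deriv_matrix(spec, [y])[0]


def monotonicity_constraints(spec: BasisSpec) -> np.ndarray:
    """Matrix C with C theta >= 0 encoding monotone nondecreasing h.

    bernstein / ordinal_steps: first differences of successive coefficients;
    linear: positivity of the slope 1/sigma; loglinear: positivity of the
    log-coefficient; binary_intercept: the empty system (free intercept).
    """
    P = spec.n_param
    if spec.kind in ("bernstein", "ordinal_steps"):
        if P == 1:
            return np.zeros((0, 1))
        C = np.zeros((P - 1, P))
        idx = np.arange(P - 1)
        C[idx, idx] = -1.0
        C[idx, idx + 1] = 1.0
        return C
    if spec.kind == "linear":
        return np.array([[1.0, 0.0]])
    if spec.kind == "loglinear":
        return np.array([[0.0, 1.0]])
    return np.zeros((0, 1))


def default_support(y_lower: np.ndarray, y_upper: np.ndarray) -> tuple[float, float]:
    """Support rule: the exact range of the finite observed bounds."""
    finite = np.concatenate([y_lower[np.isfinite(y_lower)], y_upper[np.isfinite(y_upper)]])
    if finite.size == 0:
        raise ValueError("no finite response bounds to infer a support from")
    return float(finite.min()), float(finite.max())
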