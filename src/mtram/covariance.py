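"""Structured latent covariance of the Gaussian copula.

The transformed responses of cluster i follow N(0, Sigma_i) with

    Sigma_i(gamma) = U_i L(gamma) L(gamma)' U_i' + I,

where U_i is the random-effect design (a column of ones for a cluster
random intercept, columns (1, t_ij) for a random intercept and slope) and
L(gamma) is an unstructured lower-triangular Cholesky factor filled
row-wise from gamma, with nonnegative diagonal.  The square roots of the
diagonal of Sigma_i enter the model as the scaling D_i responsible for the
shrinkage of marginal effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RandomEffectDesign", "cholesky_factor", "n_gamma", "sigma_build",
           "scale_diag", "marginal_scale"]


@dataclass(frozen=True)
class RandomEffectDesign:
    """Random-effect structure: 'intercept' (R=1) or 'intercept_slope' (R=2)."""

    kind: str

    def __post_init__(self):
        if self.kind not in ("intercept", "intercept_slope"):
            raise ValueError(f"unknown random-effect design {self.kind!r}")

    @property
    def R(self) -> int:
        return 1 if self.kind == "intercept" else 2

    def U(self, n: int, time: np.ndarray | None = None) -> np.ndarray:
        """Design rows U_i for a cluster of size n observed at the given times."""
        ones = np.ones(n)
        if self.kind == "intercept":
            return ones[:, None]
        if time is None:
            raise ValueError("intercept_slope design needs observation times")
        time = np.asarray(time, dtype=float)
        if time.shape != (n,) or not np.all(np.isfinite(time)):
            raise ValueError("times must be a finite vector of the cluster size")
        return np.column_stack([ones, time])


def n_gamma(R: int) -> int:
    """Number of free covariance parameters M = R(R+1)/2."""
    return R * (R + 1) // 2


def cholesky_factor(gamma, R: int) -> np.ndarray:
    """Lower-triangular L(gamma), filled row-wise: (g1), or [[g1,0],[g2,g3]]."""
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if gamma.shape != (n_gamma(R),):
        raise ValueError(f"gamma must have length R(R+1)/2 = {n_gamma(R)} for R={R}")
    L = np.zeros((R, R))
    L[np.tril_indices(R)] = gamma
    if np.any(np.diag(L) < 0):
        raise ValueError("diagonal of the Cholesky factor must be nonnegative")
    return L


def sigma_build(design: RandomEffectDesign, gamma, n: int,
                time: np.ndarray | None = None) -> np.ndarray:
    """Sigma_i = U L L' U' + I for one cluster."""
    L = cholesky_factor(gamma, design.R)
    U = design.U(n, time)
    G = U @ L
    return G @ G.T + np.eye(n)


def scale_diag(design: RandomEffectDesign, gamma, n: int,
               time: np.ndarray | None = None) -> np.ndarray:
    """Diagonal scaling D_i = diag(Sigma_i)^{1/2} as a vector of length n."""
    L = cholesky_factor(gamma, design.R)
    U = design.U(n, time)
    return np.sqrt(np.sum((U @ L) ** 2, axis=1) + 1.0)


def marginal_scale(u, gamma) -> float:
    """sqrt(u' L L' u + 1), the marginal-effect shrinkage denominator at design row u."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    R = u.shape[0]
    L = cholesky_factor(gamma, R)
    v = L.T @ u
    return float(np.sqrt(v @ v + 1.0))
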