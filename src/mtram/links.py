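"""Inverse link distributions F.

A transformation model P(Y <= y | x) = F(h(y) - x'b) is defined on the
scale of a fixed continuous distribution function F with log-concave
density f.  The choice of F fixes the interpretation of the linear
predictor: conditional mean shift (probit), log-odds ratio (logit),
log-hazard ratio (cloglog, minimum extreme value) or log-reverse-time
hazard ratio (loglog, maximum extreme value).

All four families evaluate cdf, log-cdf, density, log-density, the
derivative of the log-density and the quantile function in a numerically
stable way far into the tails (log-space formulas for |z| large), which
the copula likelihood needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special

__all__ = ["LinkFamily", "get_link", "LINKS", "inverse_link", "link_density", "link_quantile"]

logger = logging.getLogger(__name__)

# probabilities fed to the standard-normal quantile inside the latent
# transform are clipped to this range; Phi^{-1}(F(.)) overflows otherwise
_PCLIP = 1e-15


def _log1mexp(a: np.ndarray) -> np.ndarray:
    """log(1 - exp(a)) for a <= 0, stable near both ends."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    near = a > -np.log(2.0)
    out[near] = np.log(-np.expm1(a[near]))
    out[~near] = np.log1p(-np.exp(a[~near]))
    return out


@dataclass(frozen=True)
class LinkFamily:
    """A fixed inverse link distribution F with density f and quantile F^{-1}."""

    name: str
    cdf: Callable[[np.ndarray], np.ndarray]
    logcdf: Callable[[np.ndarray], np.ndarray]
    pdf: Callable[[np.ndarray], np.ndarray]
    logpdf: Callable[[np.ndarray], np.ndarray]
    dlogpdf: Callable[[np.ndarray], np.ndarray]
    quantile: Callable[[np.ndarray], np.ndarray]
    scale_name: str = field(default="linear predictor")

    def __repr__(self) -> str:  # pragma: no cover
        return f"LinkFamily({self.name!r})"


def _probit() -> LinkFamily:
    return LinkFamily(
        name="probit",
        cdf=special.ndtr,
        logcdf=special.log_ndtr,
        pdf=lambda z: np.exp(-0.5 * np.square(z)) / np.sqrt(2.0 * np.pi),
        logpdf=lambda z: -0.5 * np.square(z) - 0.5 * np.log(2.0 * np.pi),
        dlogpdf=lambda z: -np.asarray(z, dtype=float),
        quantile=special.ndtri,
        scale_name="conditional mean / probit",
    )


def _logit() -> LinkFamily:
    return LinkFamily(
        name="logit",
        cdf=special.expit,
        logcdf=lambda z: special.log_expit(z),
        pdf=lambda z: special.expit(z) * special.expit(-z),
        logpdf=lambda z: special.log_expit(z) + special.log_expit(-z),
        dlogpdf=lambda z: 1.0 - 2.0 * special.expit(z),
        quantile=special.logit,
        scale_name="log-odds ratio",
    )


def _cloglog() -> LinkFamily:
    # Gompertz / minimum extreme value: F(z) = 1 - exp(-exp(z))
    def cdf(z):
        return -np.expm1(-np.exp(np.asarray(z, dtype=float)))

    def logcdf(z):
        return _log1mexp(-np.exp(np.asarray(z, dtype=float)))

    def logpdf(z):
        z = np.asarray(z, dtype=float)
        return z - np.exp(z)

    def quantile(p):
        return np.log(-np.log1p(-np.asarray(p, dtype=float)))

    return LinkFamily(
        name="cloglog",
        cdf=cdf,
        logcdf=logcdf,
        pdf=lambda z: np.exp(logpdf(z)),
        logpdf=logpdf,
        dlogpdf=lambda z: 1.0 - np.exp(np.asarray(z, dtype=float)),
        quantile=quantile,
        scale_name="log-hazard ratio",
    )


def _loglog() -> LinkFamily:
    # Gumbel / maximum extreme value: F(z) = exp(-exp(-z))
    def logcdf(z):
        return -np.exp(-np.asarray(z, dtype=float))

    def logpdf(z):
        z = np.asarray(z, dtype=float)
        return -z - np.exp(-z)

    def quantile(p):
        return -np.log(-np.log(np.asarray(p, dtype=float)))

    return LinkFamily(
        name="loglog",
        cdf=lambda z: np.exp(logcdf(z)),
        logcdf=logcdf,
        pdf=lambda z: np.exp(logpdf(z)),
        logpdf=logpdf,
        dlogpdf=lambda z: np.exp(-np.asarray(z, dtype=float)) - 1.0,
        quantile=quantile,
        scale_name="log-reverse-time hazard ratio",
    )


LINKS: dict[str, LinkFamily] = {
    "probit": _probit(),
    "logit": _logit(),
    "cloglog": _cloglog(),
    "loglog": _loglog(),
}


def get_link(name: str) -> LinkFamily:
    """Look up a link family by name ('probit', 'logit', 'cloglog', 'loglog')."""
    try:
        return LINKS[name]
    except KeyError:
        raise ValueError(
            f"unknown link family {name!r}; choose one of {sorted(LINKS)}"
        ) from None


def inverse_link(family: LinkFamily | str, z):
    """F(z): map a linear-predictor value to a probability."""
    fam = get_link(family) if isinstance(family, str) else family
    return fam.cdf(np.asarray(z, dtype=float))


def link_density(family: LinkFamily | str, z):
    """f(z) = dF/dz."""
    fam = get_link(family) if isinstance(family, str) else family
    return fam.pdf(np.asarray(z, dtype=float))


def link_quantile(family: LinkFamily | str, p):
    """F^{-1}(p) for p in (0,1); p at 0 or 1 raises (use +-inf bounds instead)."""
    fam = get_link(family) if isinstance(family, str) else family
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("quantile requires p strictly inside (0, 1); "
                         "represent boundary cases via infinite censoring bounds")
    return fam.quantile(p)


def normal_quantile_of(family: LinkFamily, z: np.ndarray) -> np.ndarray:
    """Phi^{-1}(F(z)) with tail clipping, the elementwise core of the latent map.

    For the probit family this is the identity.  Otherwise probabilities are
    clipped to [1e-15, 1-1e-15] before applying the normal quantile; clipping
    events are counted through the module logger.
    """
    z = np.asarray(z, dtype=float)
    if family.name == "probit":
        return z
    p = family.cdf(z)
    n_clip = int(np.count_nonzero(((p < _PCLIP) | (p > 1.0 - _PCLIP)) & np.isfinite(z)))
    if n_clip:
        logger.debug("normal_quantile_of: clipped %d probabilities to [%g, 1-%g]",
                     n_clip, _PCLIP, _PCLIP)
    q = special.ndtri(np.clip(p, _PCLIP, 1.0 - _PCLIP))
    # keep infinities from infinite censoring bounds
    q = np.where(np.isneginf(z), -np.inf, q)
    q = np.where(np.isposinf(z), np.inf, q)
    return q
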