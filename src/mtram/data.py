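"""Long-format clustered data container.

One row per observation; rows are grouped into independent clusters.  A
response is either exact (lower == upper, a density contribution) or an
interval (lower, upper] with -inf / +inf allowed, which covers binary,
ordinal, right- and interval-censored responses.  Within a cluster all
elements must be of the same kind; mixing exact and censored observations
in one cluster is not supported by the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariance import RandomEffectDesign

__all__ = ["ClusteredData"]


@dataclass
class ClusteredData:
    """Validated clustered observations, stably sorted by cluster."""

    lower: np.ndarray            # (n,) lower response bounds, -inf allowed
    upper: np.ndarray            # (n,) upper response bounds, +inf allowed
    X: np.ndarray                # (n, Q) fixed-effect design
    cluster: np.ndarray          # (n,) integer cluster codes, contiguous blocks
    time: np.ndarray | None = None
    strata: np.ndarray | None = None    # (n,) integer stratum codes
    cluster_labels: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()

    # derived
    starts: np.ndarray = field(init=False)   # first row index of each cluster
    sizes: np.ndarray = field(init=False)

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.lower.shape[0]:
            self.X = self.X.reshape(self.lower.shape[0], -1)
        self.cluster = np.asarray(self.cluster)
        n = self.lower.shape[0]
        if not (self.upper.shape == (n,) and self.cluster.shape == (n,)):
            raise ValueError("lower, upper and cluster must have equal length")
        if np.any(self.lower > self.upper):
            bad = np.nonzero(self.lower > self.upper)[0][:5]
            raise ValueError(f"lower > upper at rows {bad.tolist()}")
        # stable sort into contiguous clusters
        codes, labels = pd.factorize(self.cluster, sort=False)
        order = np.argsort(codes, kind="stable")
        if not np.array_equal(order, np.arange(n)):
            self.lower = self.lower[order]
            self.upper = self.upper[order]
            self.X = self.X[order]
            codes = codes[order]
            if self.time is not None:
                self.time = np.asarray(self.time, dtype=float)[order]
            if self.strata is not None:
                self.strata = np.asarray(self.strata)[order]
        self.cluster = codes
        if self.cluster_labels is None:
            self.cluster_labels = np.asarray(labels)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
        if self.strata is not None:
            s_codes, s_labels = pd.factorize(self.strata, sort=True)
            self.strata = s_codes
            self._strata_labels = np.asarray(s_labels)
        else:
            self._strata_labels = None
        self.starts = np.concatenate([[0], 1 + np.nonzero(np.diff(self.cluster))[0]])
        self.sizes = np.diff(np.concatenate([self.starts, [n]]))

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.lower.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.starts.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_strata(self) -> int:
        return 1 if self.strata is None else int(self.strata.max()) + 1

    @property
    def exact(self) -> np.ndarray:
        """Per-row flag: exact observation (lower == upper, both finite)."""
        return np.isfinite(self.lower) & (self.lower == self.upper)

    @property
    def all_exact(self) -> bool:
        return bool(np.all(self.exact))

    @property
    def all_bounded(self) -> bool:
        return not np.any(self.exact)

    @property
    def y(self) -> np.ndarray:
        """Exact response values; raises when any observation is censored."""
        if not self.all_exact:
            raise ValueError("data contain censored observations; no exact response vector")
        return self.lower

    def validate_kind(self, likelihood_kind: str) -> None:
        ex = self.exact
        if likelihood_kind == "continuous":
            if not self.all_exact:
                raise ValueError("continuous likelihood requires all-exact responses")
            return
        if np.any(ex):
            # clusters mixing exact and bounded rows are rejected outright
            raise ValueError(
                "censored likelihood requires interval responses; got exact rows "
                "(mixing exact and censored observations is not supported)")

    def design_times(self, design: RandomEffectDesign, i: int) -> np.ndarray | None:
        if design.kind == "intercept":
            return None
        if self.time is None:
            raise ValueError("intercept_slope design needs a time column")
        s, m = self.starts[i], self.sizes[i]
        return self.time[s:s + m]

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, cluster: str,
                   response: str | None = None,
                   lower: str | None = None, upper: str | None = None,
                   covariates: tuple[str, ...] = (),
                   time: str | None = None, strata: str | None = None) -> "ClusteredData":
        """Build from a long-format data frame (one row per observation)."""
        missing = [c for c in ((cluster,) + tuple(covariates)
                               + ((response,) if response else ())
                               + ((lower,) if lower else ())
                               + ((upper,) if upper else ())
                               + ((time,) if time else ())
                               + ((strata,) if strata else ())) if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if response is not None:
            lo = pd.to_numeric(df[response], errors="raise").to_numpy(dtype=float)
            hi = lo.copy()
        else:
            if lower is None or upper is None:
                raise ValueError("either a response column or both bound columns are required")
            lo = _parse_bounds(df[lower], -np.inf)
            hi = _parse_bounds(df[upper], np.inf)
        X = df[list(covariates)].to_numpy(dtype=float) if covariates else np.zeros((len(df), 0))
        return cls(
            lower=lo, upper=hi, X=X, cluster=df[cluster].to_numpy(),
            time=df[time].to_numpy(dtype=float) if time else None,
            strata=df[strata].to_numpy() if strata else None,
            covariate_names=tuple(covariates),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame round-trippable through ``from_frame``."""
        cols = {"cluster": np.asarray(self.cluster_labels)[self.cluster]}
        if self.all_exact:
            cols["y"] = self.lower
        else:
            cols["lower"] = self.lower
            cols["upper"] = self.upper
        if self.time is not None:
            cols["time"] = self.time
        names = self.covariate_names or tuple(f"x{q+1}" for q in range(self.n_covariates))
        for q, name in enumerate(names):
            cols[name] = self.X[:, q]
        if self.strata is not None:
            cols["stratum"] = self._strata_labels[self.strata]
        return pd.DataFrame(cols)


def _parse_bounds(col: pd.Series, sentinel: float) -> np.ndarray:
    """Parse a bound column: empty / 'Inf' / '-Inf' map to infinities."""
    raw = col.astype(object)
    out = np.empty(len(raw), dtype=float)
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            out[i] = sentinel
            continue
        s = str(v).strip()
        if s == "" or s.lower() in ("na", "nan"):
            out[i] = sentinel
        elif s.lower() in ("inf", "+inf", "infinity"):
            out[i] = np.inf
        elif s.lower() == "-inf":
            out[i] = -np.inf
        else:
            out[i] = float(s)
    return out
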