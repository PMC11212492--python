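"""CSV ingestion, YAML model configuration and report writing.

Input data are long-format comma-separated tables with a header row: one
row per observation, a cluster identifier column, either a single exact
response column or a pair of lower/upper bound columns (with the sentinels
``-Inf`` / ``Inf`` or empty cells for infinite bounds), optional time and
stratum columns, and covariate columns.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ClusteredData
from .estimation import FittedMTRAM, ModelSpec
from .basis import BasisSpec

__all__ = ["LongTableSchema", "read_long_table", "write_long_table",
           "load_config", "write_fit_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LongTableSchema:
    """Column mapping of a long-format table."""

    cluster_column: str = "cluster"
    response_column: str | None = "y"
    lower_column: str | None = None
    upper_column: str | None = None
    time_column: str | None = None
    strata_column: str | None = None
    covariate_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.response_column is None and (self.lower_column is None
                                             or self.upper_column is None):
            raise ValueError("schema needs a response column or both bound columns")


def read_long_table(path, schema: LongTableSchema) -> ClusteredData:
    """Read and validate a long-format CSV into ClusteredData."""
    df = pd.read_csv(path, keep_default_na=True)
    data = ClusteredData.from_frame(
        df, cluster=schema.cluster_column,
        response=schema.response_column,
        lower=schema.lower_column, upper=schema.upper_column,
        covariates=schema.covariate_columns,
        time=schema.time_column, strata=schema.strata_column)
    logger.info("read %d observations in %d clusters (sizes %d..%d) from %s",
                data.n_obs, data.n_clusters, data.sizes.min(), data.sizes.max(), path)
    return data


def write_long_table(data: ClusteredData, path) -> None:
    """Write ClusteredData back to CSV (round-trips through read_long_table)."""
    df = data.to_frame()
    if not data.all_exact:
        for col in ("lower", "upper"):
            df[col] = df[col].map(
                lambda v: "-Inf" if np.isneginf(v) else ("Inf" if np.isposinf(v)
                                                         else repr(float(v))))
    df.to_csv(path, index=False)


def infer_schema(df_columns, *, cluster: str, response: str | None,
                 lower: str | None, upper: str | None, time: str | None,
                 strata: str | None, covariates) -> LongTableSchema:
    if covariates:
        cov = tuple(covariates)
    else:
        reserved = {cluster, response, lower, upper, time, strata} - {None}
        cov = tuple(c for c in df_columns if c not in reserved)
    return LongTableSchema(cluster_column=cluster, response_column=response,
                           lower_column=lower, upper_column=upper,
                           time_column=time, strata_column=strata,
                           covariate_columns=cov)


def load_config(path) -> dict:
    """Read a declarative YAML config (model + data sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def model_spec_from_config(cfg: dict) -> ModelSpec:
    m = cfg.get("model", cfg)
    kw = {}
    for key in ("link", "basis_kind", "order", "design"):
        if key in m:
            kw[key] = m[key]
    if "support" in m:
        lo, hi = m["support"]
        kw["basis"] = BasisSpec(m.get("basis_kind", "bernstein"),
                                m.get("order", 6), (float(lo), float(hi)))
    return ModelSpec(**kw)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def write_fit_report(fit: FittedMTRAM, path, machine_path=None) -> None:
    """Plain-text summary plus an optional key/value results file."""
    Path(path).write_text(fit.summary() + "\n")
    if machine_path is not None:
        pv = fit.params
        lines = [f"loglik\t{fit.loglik!r}"]
        lines += [f"theta{k+1}\t{v!r}" for k, v in enumerate(pv.theta)]
        names = fit.engine.data.covariate_names or tuple(
            f"x{q+1}" for q in range(pv.beta.shape[0]))
        lines += [f"beta_{n}\t{v!r}" for n, v in zip(names, pv.beta)]
        lines += [f"gamma{k+1}\t{v!r}" for k, v in enumerate(pv.gamma)]
        Path(machine_path).write_text("\n".join(lines) + "\n")
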