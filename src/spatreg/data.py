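"""Site-table ingestion, prediction output, and run configuration.

The carrier object for the pipeline is :class:`SpatialDataset`: site ids,
planar x/y coordinates, a numeric response, optional region labels, and a
table of numeric covariates.  Coordinates are taken as-is; longitude/latitude
must be projected (e.g. to an equal-area CRS in km) before input.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = ["SpatialDataset", "read_sites", "write_predictions", "RunConfig",
           "load_config"]


@dataclass
class SpatialDataset:
    """Tabular spatial data: coordinates + response + covariates (+ regions)."""

    site_id: np.ndarray
    coords: np.ndarray
    response: np.ndarray
    covariates: pd.DataFrame
    region: np.ndarray | None = None

    def __post_init__(self):
        self.site_id = np.asarray(self.site_id)
        self.coords = np.asarray(self.coords, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        n = len(self.site_id)
        if len(np.unique(self.site_id)) != n:
            raise ValueError("site ids must be unique")
        if self.coords.shape != (n, 2) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite and n x 2")
        if len(self.response) != n or len(self.covariates) != n:
            raise ValueError("length mismatch among dataset components")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
            if len(self.region) != n:
                raise ValueError("region labels length mismatch")

    @property
    def n(self) -> int:
        return len(self.site_id)

    def subset(self, idx) -> "SpatialDataset":
        idx = np.asarray(idx)
        return SpatialDataset(
            self.site_id[idx], self.coords[idx], self.response[idx],
            self.covariates.iloc[idx].reset_index(drop=True),
            None if self.region is None else self.region[idx],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, response: str = "y",
                   x: str = "x", y: str = "y_coord", id_col: str | None = None,
                   region: str | None = None, covariates=None):
        ids = df[id_col].to_numpy() if id_col else np.arange(len(df))
        reserved = {response, x, y, id_col, region} - {None}
        cov_cols = covariates if covariates is not None else [
            c for c in df.columns if c not in reserved
        ]
        return cls(ids, df[[x, y]].to_numpy(dtype=float),
                   df[response].to_numpy(dtype=float),
                   df[list(cov_cols)].reset_index(drop=True),
                   None if region is None else df[region].to_numpy())


def read_sites(path, schema: dict) -> SpatialDataset:
    """Read a site CSV under a column schema.

    ``schema`` names the mandatory ``id``, ``x``, ``y`` and ``response``
    columns, optionally ``region`` and an explicit ``covariates`` list
    (default: every remaining numeric column).  Rows with a missing response
    are dropped with a warning; missing covariate values are an error.
    """
    df = pd.read_csv(path)
    mandatory = ["id", "x", "y", "response"]
    missing_keys = [k for k in mandatory if k not in schema]
    if missing_keys:
        raise ValueError(f"schema lacks keys {missing_keys}")
    named = [schema[k] for k in mandatory]
    if schema.get("region"):
        named.append(schema["region"])
    absent = [c for c in named if c not in df.columns]
    if absent:
        raise ValueError(f"missing mandatory column(s) {absent} in {path}")
    n0 = len(df)
    df = df.dropna(subset=[schema["response"]]).reset_index(drop=True)
    if len(df) < n0:
        warnings.warn(f"dropped {n0 - len(df)} row(s) with missing response",
                      stacklevel=2)
    cov_cols = schema.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns if c not in named
                    and pd.api.types.is_numeric_dtype(df[c])]
    else:
        absent = [c for c in cov_cols if c not in df.columns]
        if absent:
            raise ValueError(f"missing covariate column(s) {absent}")
    covs = df[list(cov_cols)]
    if covs.isna().any().any():
        bad = covs.columns[covs.isna().any()].tolist()
        raise ValueError(f"missing covariate values in {bad}; no imputation "
                         "is performed")
    return SpatialDataset(
        df[schema["id"]].to_numpy(),
        df[[schema["x"], schema["y"]]].to_numpy(dtype=float),
        df[schema["response"]].to_numpy(dtype=float),
        covs.reset_index(drop=True),
        df[schema["region"]].to_numpy() if schema.get("region") else None,
    )


def write_predictions(site_id, coords, result, path, clamped=None) -> pd.DataFrame:
    """Write a prediction CSV: site_id, x, y, pred, se, lower, upper, clamped."""
    coords = np.asarray(coords, dtype=float)
    out = pd.DataFrame({
        "site_id": np.asarray(site_id),
        "x": coords[:, 0],
        "y": coords[:, 1],
        "pred": result.mean,
        "se": result.se if result.se is not None else np.nan,
        "lower": result.lower,
        "upper": result.upper,
        "clamped": clamped if clamped is not None else np.zeros(len(result),
                                                               dtype=bool),
    })
    out.to_csv(path, index=False)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration with study defaults."""

    lambda1_grid: tuple = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0)
    zero_threshold: float = 0.02
    kfolds: int = 10
    n_trees: int = 1000
    mtry: int | None = None
    min_node_size: int = 5
    knots: int | None = None  # None -> min(100, n/5) by k-means
    seed: int = 0
    interval_level: float = 0.90
    clamp_bounds: tuple | None = None

    def __post_init__(self):
        if self.kfolds < 2:
            raise ValueError("kfolds: must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees: must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry: must be >= 1 (or null for p/3)")
        if self.min_node_size < 1:
            raise ValueError("min_node_size: must be >= 1")
        if not 0.0 < self.interval_level < 1.0:
            raise ValueError("interval_level: must be in (0, 1)")
        if not 0.0 <= self.zero_threshold < 1.0:
            raise ValueError("zero_threshold: must be in [0, 1)")
        if self.clamp_bounds is not None:
            lo, hi = self.clamp_bounds
            if lo > hi:
                raise ValueError("clamp_bounds: must be ordered (lo, hi)")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON configuration, applying defaults.

    Unknown keys are rejected with the offending name; value constraints are
    reported with the key they violate.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            text = fh.read()
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text)) or {}
    if overrides:
        raw.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    for key in ("lambda1_grid", "clamp_bounds"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
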