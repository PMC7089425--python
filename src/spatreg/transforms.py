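"""Box-Cox covariate transformation estimation for spatial regression.

Environmental covariates are frequently skewed and often zero-inflated
(an atom of exact zeros plus a skewed positive part).  To linearize their
relationship with the response before regression modelling, each covariate
is transformed with a shifted Box-Cox power

    g(x; l1, l2) = ((x + l2)^l1 - 1) / l1    (l1 != 0)
                 = log(x + l2)               (l1 == 0),

and the transformation is chosen per covariate by AIC over a grid of
(l1, l2) and a small family of single-covariate linear models.  Covariates
with more than 2% exact zeros are treated as zero-inflated and compete
over indicator-based forms (zero/nonzero indicator, indicator x Box-Cox
interaction, or both); the rest compete over a linear or quadratic
polynomial in g.  Spatial autocorrelation is deliberately ignored at this
stage: each candidate is an ordinary least-squares fit, which keeps the grid
search fast and is accurate enough to rank functional forms.

Selected transformations are frozen into :class:`TransformSpec` objects and
expanded into a :class:`DesignMatrix` (with intercept and region dummy
columns) used by both the linear and spatial models; prediction-time data
re-uses the frozen parameters, never re-estimating them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "boxcox", "is_zero_inflated", "score_candidate", "select_transformations",
    "build_design_matrix", "TransformSpec", "DesignMatrix", "DesignBuilder",
    "ZERO_INFLATED_FORMS", "CONTINUOUS_FORMS", "DEFAULT_LAMBDA1_GRID",
    "transform_report",
]

logger = logging.getLogger(__name__)

ZERO_INFLATED_FORMS = ("IND", "IND_X_BC", "IND_PLUS_BC")
CONTINUOUS_FORMS = ("BC_LINEAR", "BC_QUAD")
# exponent grid spans 0..3; log transform included as l1 = 0
DEFAULT_LAMBDA1_GRID = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0)

_FORM_COMPLEXITY = {"IND": 0, "IND_X_BC": 1, "IND_PLUS_BC": 2,
                    "BC_LINEAR": 0, "BC_QUAD": 1}


def boxcox(x, lambda1: float, lambda2: float = 0.0) -> np.ndarray:
    """Shifted Box-Cox transform; requires x + lambda2 > 0 elementwise."""
    x = np.asarray(x, dtype=float)
    shifted = x + lambda2
    if np.any(shifted <= 0):
        raise ValueError(
            f"Box-Cox domain violation: min(x + lambda2) = {shifted.min():.6g}"
        )
    if lambda1 == 0:
        return np.log(shifted)
    return (shifted ** lambda1 - 1.0) / lambda1


def is_zero_inflated(x, threshold: float = 0.02) -> bool:
    """True iff the proportion of exact zeros strictly exceeds ``threshold``."""
    x = np.asarray(x, dtype=float)
    return bool(np.mean(x == 0) > threshold)


@dataclass(frozen=True)
class TransformSpec:
    """A selected per-covariate transformation with its AIC."""

    covariate: str
    form: str
    lambda1: float | None
    lambda2: float | None
    aic: float
    zero_inflated: bool

    def __post_init__(self):
        allowed = ZERO_INFLATED_FORMS if self.zero_inflated else CONTINUOUS_FORMS
        if self.form not in allowed:
            raise ValueError(
                f"form {self.form!r} invalid for "
                f"{'zero-inflated' if self.zero_inflated else 'continuous'} "
                f"covariate {self.covariate!r}"
            )


def _candidate_columns(x: np.ndarray, form: str, lambda1, lambda2):
    """Design columns (without intercept) for a candidate form.

    For zero-inflated forms the Box-Cox part is evaluated only on the
    nonzero support and multiplied by the indicator.
    """
    if form == "IND":
        return [(x != 0).astype(float)], ["ind"]
    if form in ("IND_X_BC", "IND_PLUS_BC"):
        ind = (x != 0).astype(float)
        g = np.zeros_like(x, dtype=float)
        nz = x != 0
        g[nz] = boxcox(x[nz], lambda1, lambda2)
        tag = f"bc({lambda1:g},{lambda2:g})xind"
        if form == "IND_X_BC":
            return [g], [tag]
        return [ind, g], ["ind", tag]
    g = boxcox(x, lambda1, lambda2)
    tag = f"bc({lambda1:g},{lambda2:g})"
    if form == "BC_LINEAR":
        return [g], [tag]
    if form == "BC_QUAD":
        return [g, g ** 2], [tag, tag + "^2"]
    raise ValueError(f"unknown transformation form {form!r}")


def score_candidate(y, x, form: str, lambda1=None, lambda2=None):
    """OLS fit of a single-covariate candidate model and its AIC.

    AIC uses the Gaussian profile form n*log(RSS/n) + 2*(k + 1), with k the
    number of regression coefficients (including the intercept); only AIC
    differences within a covariate's competition matter, so the additive
    constant is fixed by convention.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant covariate cannot be scored")
    cols, _ = _candidate_columns(x, form, lambda1, lambda2)
    X = np.column_stack([np.ones_like(y)] + cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n, k = len(y), X.shape[1]
    if rss <= 0:
        raise ValueError("perfect fit (RSS = 0): AIC undefined")
    aic = n * np.log(rss / n) + 2.0 * (k + 1)
    return {"beta": beta, "rss": rss, "k": k, "rank": rank, "aic": aic}


def _lambda2_candidates(support: np.ndarray) -> list[float]:
    """Shift candidates keeping x + lambda2 > 0 on the evaluated support."""
    mn = float(support.min())
    cands = [0.0, 1.0]
    positive = support[support > 0]
    if positive.size:
        cands.append(float(positive.min()) / 2.0)
    return sorted({l2 for l2 in cands if mn + l2 > 0})


def select_transformations(y, X_raw: pd.DataFrame,
                           lambda1_grid=DEFAULT_LAMBDA1_GRID,
                           zero_threshold: float = 0.02) -> list[TransformSpec]:
    """Per-covariate AIC selection of transformation form and parameters.

    Each covariate is scored independently (OLS); the minimizing
    (form, lambda1, lambda2) is returned per covariate, with deterministic
    tie-breaks (smaller lambda1, then simpler form).  Covariates that fail
    to score (e.g. constant columns) are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    specs: list[TransformSpec] = []
    for name in X_raw.columns:
        x = np.asarray(X_raw[name], dtype=float)
        try:
            specs.append(_select_one(y, x, str(name), lambda1_grid,
                                     zero_threshold))
        except ValueError as exc:
            warnings.warn(f"skipping covariate {name!r}: {exc}", stacklevel=2)
    return specs


def _select_one(y, x, name, lambda1_grid, zero_threshold) -> TransformSpec:
    zi = is_zero_inflated(x, zero_threshold)
    support = x[x != 0] if zi else x
    if support.size == 0:
        raise ValueError("no nonzero support")
    candidates = []
    if zi:
        candidates.append(("IND", None, None))
        l2s = _lambda2_candidates(support)
        for form in ("IND_X_BC", "IND_PLUS_BC"):
            for l1 in lambda1_grid:
                for l2 in l2s:
                    candidates.append((form, l1, l2))
    else:
        l2s = _lambda2_candidates(support)
        for form in CONTINUOUS_FORMS:
            for l1 in lambda1_grid:
                for l2 in l2s:
                    candidates.append((form, l1, l2))
    best = None
    for form, l1, l2 in candidates:
        try:
            aic = score_candidate(y, x, form, l1, l2)["aic"]
        except (ValueError, FloatingPointError):
            continue
        key = (aic, l1 if l1 is not None else -1.0, _FORM_COMPLEXITY[form])
        if best is None or key < best[0]:
            best = (key, form, l1, l2, aic)
    if best is None:
        raise ValueError("no scoreable candidate form")
    _, form, l1, l2, aic = best
    logger.debug("covariate %s: selected %s l1=%s l2=%s (AIC %.3f)",
                 name, form, l1, l2, aic)
    return TransformSpec(name, form, l1, l2, aic, zi)


@dataclass
class DesignMatrix:
    """Named design matrix with protection and removal-order metadata.

    ``protected`` columns (intercept, region dummies) are never candidates
    for elimination; ``requires_removed`` encodes weak hierarchy for
    two-column transformations: the higher-order column (quadratic or
    Box-Cox part) must leave the model before its base column may.
    """

    values: np.ndarray
    names: list[str]
    protected: frozenset = frozenset()
    requires_removed: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values/names shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix contains non-finite entries")

    @property
    def shape(self):
        return self.values.shape

    def select(self, keep: list[str]) -> "DesignMatrix":
        idx = [self.names.index(c) for c in keep]
        req = {c: p for c, p in self.requires_removed.items()
               if c in keep and p in keep}
        return DesignMatrix(self.values[:, idx], list(keep),
                            self.protected & frozenset(keep), req)

    def removable(self, current: list[str] | None = None) -> list[str]:
        """Columns currently eligible for elimination (hierarchy-aware)."""
        cols = current if current is not None else self.names
        blocked = set()
        for col in cols:
            partner = self.requires_removed.get(col)
            if partner is not None and partner in cols:
                blocked.add(col)
        return [c for c in cols if c not in self.protected and c not in blocked]

    def to_frame(self):
        return pd.DataFrame(self.values, columns=self.names)


@dataclass
class DesignBuilder:
    """Expands raw covariates into a design matrix under frozen specs.

    Region labels are one-hot encoded with reference-level coding against
    the levels observed at construction; an unseen region at prediction time
    is an error.  Built once on training data, then re-applied unchanged.
    """

    specs: list
    region_levels: list | None = None
    include_intercept: bool = True

    @classmethod
    def from_training(cls, specs, region=None, include_intercept=True):
        levels = None
        if region is not None:
            levels = sorted(pd.unique(np.asarray(region, dtype=object)))
        return cls(list(specs), levels, include_intercept)

    def build(self, X_raw: pd.DataFrame, region=None) -> DesignMatrix:
        n = len(X_raw)
        cols, names = [], []
        protected = set()
        requires: dict = {}
        if self.include_intercept:
            cols.append(np.ones(n))
            names.append("Intercept")
            protected.add("Intercept")
        if self.region_levels is not None:
            if region is None:
                raise ValueError("model was built with region labels")
            region = np.asarray(region, dtype=object)
            unknown = set(region) - set(self.region_levels)
            if unknown:
                raise ValueError(f"unknown region label(s): {sorted(unknown)}")
            for lev in self.region_levels[1:]:  # first level is the reference
                cols.append((region == lev).astype(float))
                names.append(f"region[{lev}]")
                protected.add(f"region[{lev}]")
        for spec in self.specs:
            x = np.asarray(X_raw[spec.covariate], dtype=float)
            sub, tags = _candidate_columns(x, spec.form, spec.lambda1,
                                           spec.lambda2)
            colnames = [f"{spec.covariate}__{t}" for t in tags]
            cols.extend(sub)
            names.extend(colnames)
            if spec.form == "BC_QUAD":
                requires[colnames[0]] = colnames[1]  # linear after quadratic
            elif spec.form == "IND_PLUS_BC":
                requires[colnames[0]] = colnames[1]  # indicator after BC part
        return DesignMatrix(np.column_stack(cols) if cols else np.empty((n, 0)),
                            names, frozenset(protected), requires)


def build_design_matrix(X_raw: pd.DataFrame, specs, region=None,
                        include_intercept: bool = True) -> DesignMatrix:
    """One-shot design construction on training data (see DesignBuilder)."""
    return DesignBuilder.from_training(specs, region, include_intercept) \
        .build(X_raw, region)


def transform_report(specs, X_raw: pd.DataFrame) -> pd.DataFrame:
    """Audit table of selected transformations per covariate."""
    rows = []
    for s in specs:
        x = np.asarray(X_raw[s.covariate], dtype=float)
        rows.append({
            "covariate": s.covariate,
            "zero_proportion": float(np.mean(x == 0)),
            "zero_inflated": s.zero_inflated,
            "form": s.form,
            "lambda1": s.lambda1,
            "lambda2": s.lambda2,
            "aic": s.aic,
        })
    return pd.DataFrame(rows)
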