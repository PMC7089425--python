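"""Two-phase backward covariate selection for the spatial linear model.

Phase 1 runs classical backward stepwise AIC elimination on the non-spatial
linear model, which is cheap to refit and prunes the bulk of a large
candidate set.  Phase 2 takes the surviving columns into the spatial model:
at each step the least significant candidate (smallest absolute t-statistic)
is removed and the SLM refit by reduced-rank ML; the removal is kept only if
AIC does not increase.  The final model is refit by full-rank REML.

Note on the removal rule: backward elimination drops the *least* significant
term at each step.  The procedure here removes the candidate with the
smallest |t|; dropping the largest |t| would discard the strongest covariates
and cannot yield a parsimonious well-fitting model.

Intercept and region-dummy columns are protected throughout, and paired
transformation columns obey weak hierarchy (the quadratic or Box-Cox part
must leave before its base column becomes removable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .transforms import DesignMatrix

logger = logging.getLogger(__name__)

__all__ = ["SelectionTrace", "backward_stepwise_lm", "backward_select_slm"]


@dataclass
class SelectionStep:
    action: str
    column: str
    aic_before: float
    aic_after: float


@dataclass
class SelectionTrace:
    """Ordered record of eliminations with AIC bookkeeping."""

    phase: str
    steps: list = field(default_factory=list)
    final_columns: list = field(default_factory=list)

    def record(self, column: str, aic_before: float, aic_after: float):
        self.steps.append(SelectionStep("remove", column, aic_before,
                                        aic_after))
        logger.info("%s: removed %s (AIC %.3f -> %.3f)", self.phase, column,
                    aic_before, aic_after)

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "steps": [
                {"action": s.action, "column": s.column,
                 "aic_before": s.aic_before, "aic_after": s.aic_after}
                for s in self.steps
            ],
            "final_columns": list(self.final_columns),
        }


def _ols_aic(y: np.ndarray, X: np.ndarray) -> float:
    """Gaussian profile AIC n*log(RSS/n) + 2*(k + 1) of an OLS fit."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n, k = len(y), X.shape[1]
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2.0 * (k + 1)


def backward_stepwise_lm(y, X: DesignMatrix, protected=None):
    """Greedy backward AIC elimination on the non-spatial linear model.

    At each step the single removal that lowers AIC the most is taken; the
    search stops when no removal lowers AIC.  Returns (selected column
    names, SelectionTrace).
    """
    y = np.asarray(y, dtype=float)
    protected = frozenset(protected) if protected is not None else X.protected
    current = list(X.names)
    trace = SelectionTrace(phase="lm-backward")

    def aic_of(cols):
        idx = [X.names.index(c) for c in cols]
        return _ols_aic(y, X.values[:, idx])

    aic_now = aic_of(current)
    while True:
        candidates = [c for c in X.removable(current) if c not in protected]
        if not candidates:
            break
        scores = [(aic_of([c for c in current if c != cand]), cand)
                  for cand in candidates]
        best_aic, best_col = min(scores, key=lambda t: t[0])
        if best_aic < aic_now:
            current.remove(best_col)
            trace.record(best_col, aic_now, best_aic)
            aic_now = best_aic
        else:
            break
    trace.final_columns = current
    return current, trace


def backward_select_slm(y, X: DesignMatrix, coords, knots=None, protected=None,
                        ml_rank: str = "reduced", final_method: str = "reml"):
    """t-statistic-guided backward elimination on the spatial linear model.

    Iterates: fit the SLM by reduced-rank ML, remove the removable candidate
    with the smallest |t|, refit, and accept the removal only if AIC does not
    increase.  Covariance parameters are warm-started from the previous fit.
    The accepted-model AIC sequence is non-increasing by construction.  The
    final model is refit with the full-rank covariance by REML.

    Returns (final SLMResults, SelectionTrace).
    """
    from .slm import SpatialLM, default_knots

    y = np.asarray(y, dtype=float)
    protected = frozenset(protected) if protected is not None else X.protected
    coords = np.asarray(coords, dtype=float)
    if ml_rank == "reduced" and knots is None:
        knots = default_knots(coords)
    current = list(X.names)
    trace = SelectionTrace(phase="slm-backward")

    def fit_cols(cols, start=None):
        dm = X.select(cols)
        model = SpatialLM(y, dm.values, coords, exog_names=dm.names)
        return model.fit(method="ml", rank=ml_rank, knots=knots, start=start)

    fit = fit_cols(current)
    while True:
        candidates = [c for c in X.removable(current) if c not in protected]
        if not candidates:
            break
        tmap = dict(zip(fit.exog_names, np.abs(fit.tvalues)))
        ordered = sorted(candidates, key=lambda c: tmap[c])
        accepted = False
        for cand in ordered:
            trial_cols = [c for c in current if c != cand]
            try:
                trial = fit_cols(trial_cols, start=fit.cov_params_)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"skipping candidate {cand!r}: {exc}",
                              stacklevel=2)
                continue
            if trial.aic <= fit.aic:
                trace.record(cand, fit.aic, trial.aic)
                current, fit, accepted = trial_cols, trial, True
            break  # only the smallest-|t| fit-able candidate is tried per step
        if not accepted:
            break
    trace.final_columns = current
    dm = X.select(current)
    final = SpatialLM(y, dm.values, coords, exog_names=dm.names).fit(
        method=final_method, rank="full", start=fit.cov_params_
    )
    return final, trace
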