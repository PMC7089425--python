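"""Performance measures, cross-validation, and the simulation benchmark.

RMSPE and prediction-interval coverage are the two headline measures.
``kfold_cv`` embeds the entire modelling recipe — transformation estimation,
covariate selection, model fitting — inside each fold, so held-out data never
influence the selected model.  ``run_simulation_study`` benchmarks the
non-spatial linear model (LM), the REML spatial linear model (SLM), the
random forest (RF) and random forest regression kriging (RFRK) across the
eight synthetic-data conditions, averaging RMSPE and 90% interval coverage
over independent replicates, with standard errors SD/sqrt(runs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SpatialDataset
from .forest import RFRK, RandomForestQuantile
from .kriging import PredictionResult, z_multiplier
from .selection import backward_select_slm, backward_stepwise_lm
from .simulate import CASES, SimulationCase, generate_case
from .slm import SLMResults, SpatialLM
from .transforms import DesignBuilder, select_transformations

logger = logging.getLogger(__name__)

__all__ = ["rmspe", "coverage", "kfold_cv", "run_simulation_study",
           "rank_covariates_slm", "EvalReport", "LMRecipe", "SLMRecipe",
           "ForestRecipe", "RFRKRecipe"]


def rmspe(observed, predicted) -> float:
    """Root-mean-square prediction error."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size == 0:
        raise ValueError("empty input")
    if observed.shape != predicted.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def coverage(observed, lower, upper) -> float:
    """Proportion of observations strictly inside their intervals.

    Boundary values count as non-covered (strict inequalities).
    """
    observed = np.asarray(observed, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not (observed.shape == lower.shape == upper.shape):
        raise ValueError("length mismatch")
    if np.any(lower > upper):
        raise ValueError("lower bounds exceed upper bounds")
    return float(np.mean((lower < observed) & (observed < upper)))


# ---------------------------------------------------------------------------
# Model recipes: fit on a training dataset, predict with intervals on a test
# dataset.  Each returns {level: PredictionResult}.
# ---------------------------------------------------------------------------


def _design_for(train: SpatialDataset, test: SpatialDataset, transform: bool,
                lambda1_grid=None):
    """Build train/test design matrices, optionally with Box-Cox selection."""
    if transform:
        kwargs = {} if lambda1_grid is None else {"lambda1_grid": lambda1_grid}
        specs = select_transformations(train.response, train.covariates,
                                       **kwargs)
    else:
        from .transforms import TransformSpec

        specs = [
            TransformSpec(str(c), "BC_LINEAR", 1.0, 0.0, np.nan, False)
            for c in train.covariates.columns
        ]
    builder = DesignBuilder.from_training(specs, train.region)
    return (builder.build(train.covariates, train.region),
            builder.build(test.covariates, test.region), specs)


@dataclass
class LMRecipe:
    """Non-spatial linear model with normal-theory prediction intervals."""

    transform: bool = False
    select: bool = False
    label: str = "LM"

    def fit_predict(self, train, test, levels=(0.90,), seed=None):
        import statsmodels.api as sm

        dm_train, dm_test, _ = _design_for(train, test, self.transform)
        if self.select:
            cols, _ = backward_stepwise_lm(train.response, dm_train)
            dm_train, dm_test = dm_train.select(cols), dm_test.select(cols)
        fit = sm.OLS(train.response, dm_train.values).fit()
        pred = fit.get_prediction(dm_test.values)
        mean, se = pred.predicted_mean, pred.se_obs
        out = {}
        for level in levels:
            z = z_multiplier(level)
            out[level] = PredictionResult(mean, se, mean - z * se,
                                          mean + z * se, level)
        return out


@dataclass
class SLMRecipe:
    """Spatial linear model: optional transforms and two-phase selection,
    full-rank REML fit, universal-kriging intervals."""

    transform: bool = False
    select: bool = False
    label: str = "SLM"

    def fit_predict(self, train, test, levels=(0.90,), seed=None):
        dm_train, dm_test, _ = _design_for(train, test, self.transform)
        if self.select:
            cols, _ = backward_stepwise_lm(train.response, dm_train)
            dm_train, dm_test = dm_train.select(cols), dm_test.select(cols)
            fit, trace = backward_select_slm(train.response, dm_train,
                                             train.coords)
            dm_test = dm_test.select(trace.final_columns)
        else:
            fit = SpatialLM(train.response, dm_train.values, train.coords,
                            exog_names=dm_train.names).fit(method="reml",
                                                           rank="full")
        return {level: fit.predict(test.coords, dm_test.values, level=level)
                for level in levels}


@dataclass
class ForestRecipe:
    """Random forest on the raw covariates with QRF quantile intervals."""

    n_trees: int = 1000
    mtry: int | None = None
    min_node_size: int = 5
    label: str = "RF"

    def _features(self, data: SpatialDataset) -> pd.DataFrame:
        X = data.covariates.copy()
        if data.region is not None:
            dummies = pd.get_dummies(pd.Series(data.region, name="region"),
                                     prefix="region", dtype=float)
            X = pd.concat([X, dummies], axis=1)
        return X

    def fit(self, train: SpatialDataset, seed=None) -> RandomForestQuantile:
        forest = RandomForestQuantile(self.n_trees, self.mtry,
                                      self.min_node_size, seed=seed)
        return forest.fit(self._features(train), train.response)

    def fit_predict(self, train, test, levels=(0.90,), seed=None):
        forest = self.fit(train, seed=seed)
        X0 = self._features(test)
        return {level: forest.interval(X0, level=level) for level in levels}


@dataclass
class RFRKRecipe(ForestRecipe):
    """Forest mean plus simple kriging of the forest's residual field."""

    label: str = "RFRK"

    def fit_predict(self, train, test, levels=(0.90,), seed=None,
                    forest: RandomForestQuantile | None = None):
        rfrk = RFRK(forest=forest or self.fit(train, seed=seed))
        rfrk.fit(self._features(train), train.response, train.coords,
                 refit_forest=False)
        X0 = self._features(test)
        return {level: rfrk.predict(X0, test.coords, level=level)
                for level in levels}


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Aggregated prediction performance for one model recipe."""

    label: str
    rmspe: float
    pic: dict
    n: int
    per_fold: list = field(default_factory=list)
    failed_folds: list = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.failed_folds)

    def to_dict(self) -> dict:
        return {"label": self.label, "rmspe": self.rmspe,
                "coverage": {f"pic{int(l * 100)}": v
                             for l, v in self.pic.items()},
                "n": self.n, "failed_folds": self.failed_folds}


def kfold_cv(data: SpatialDataset, recipe, k: int = 10, seed: int = 0,
             levels=(0.90, 0.95)) -> EvalReport:
    """K-fold cross-validation with the full recipe embedded per fold.

    Folds are a uniform random partition under ``seed``; each observation is
    predicted exactly once.  A fold whose recipe fails is recorded and
    skipped, and the report flagged.
    """
    if data.n < k:
        raise ValueError(f"need at least k={k} observations")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(data.n) % k
    preds = {level: np.full(data.n, np.nan) for level in levels}
    lowers = {level: np.full(data.n, np.nan) for level in levels}
    uppers = {level: np.full(data.n, np.nan) for level in levels}
    failed = []
    for fold in range(k):
        test_idx = np.where(assignment == fold)[0]
        train_idx = np.where(assignment != fold)[0]
        try:
            results = recipe.fit_predict(data.subset(train_idx),
                                         data.subset(test_idx), levels=levels,
                                         seed=seed * 1000 + fold)
        except Exception as exc:  # recipe failures must not kill the CV
            warnings.warn(f"fold {fold} failed: {exc}", stacklevel=2)
            failed.append(fold)
            continue
        for level, res in results.items():
            preds[level][test_idx] = res.mean
            lowers[level][test_idx] = res.lower
            uppers[level][test_idx] = res.upper
    ok = ~np.isnan(preds[levels[0]])
    if not np.any(ok):
        raise RuntimeError("all cross-validation folds failed")
    report = EvalReport(
        label=getattr(recipe, "label", type(recipe).__name__),
        rmspe=rmspe(data.response[ok], preds[levels[0]][ok]),
        pic={level: coverage(data.response[ok], lowers[level][ok],
                             uppers[level][ok]) for level in levels},
        n=int(np.sum(ok)),
        failed_folds=failed,
    )
    return report


# ---------------------------------------------------------------------------
# Simulation study
# ---------------------------------------------------------------------------

_SIM_MODELS = ("LM", "SLM", "RF", "RFRK")


def _sim_recipes(n_trees: int):
    return {
        "LM": LMRecipe(),
        "SLM": SLMRecipe(),
        "RF": ForestRecipe(n_trees=n_trees),
        "RFRK": RFRKRecipe(n_trees=n_trees),
    }


def _run_seed(master: int, case_id: int, run: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master), int(case_id), int(run)])


def simulate_one_run(case: SimulationCase, master_seed: int, run: int,
                     models=_SIM_MODELS, level: float = 0.90,
                     n_trees: int = 1000) -> dict:
    """Generate one replicate and evaluate the requested models on it.

    The SLM uses full-rank REML with an intercept and the four untransformed
    covariates; the LM is OLS on the same design; the forest uses x1..x4.
    RF and RFRK share one fitted forest.
    """
    ss = _run_seed(master_seed, case.case_id, run)
    sim = generate_case(case, seed=ss)
    df = sim.to_frame()
    train_df, test_df = sim.split()
    covs = ["x1", "x2", "x3", "x4"]

    def as_dataset(d):
        return SpatialDataset(np.arange(len(d)), d[["x", "y_coord"]].to_numpy(),
                              d["y"].to_numpy(), d[covs].reset_index(drop=True))

    train, test = as_dataset(train_df), as_dataset(test_df)
    forest_seed = int(ss.generate_state(2)[1] % (2 ** 31))
    recipes = _sim_recipes(n_trees)
    out = {"a": sim.a, "c": sim.c}
    shared_forest = None
    for name in models:
        recipe = recipes[name]
        if name in ("RF", "RFRK") and shared_forest is None:
            shared_forest = recipe.fit(train, seed=forest_seed)
        if name == "RF":
            X0 = recipe._features(test)
            res = shared_forest.interval(X0, level=level)
        elif name == "RFRK":
            res = recipe.fit_predict(train, test, levels=(level,),
                                     forest=shared_forest)[level]
        else:
            res = recipe.fit_predict(train, test, levels=(level,),
                                     seed=forest_seed)[level]
        out[name] = {
            "rmspe": rmspe(test.response, res.mean),
            "coverage": coverage(test.response, res.lower, res.upper),
        }
    return out


def run_simulation_study(cases=None, n_runs: int = 20, models=_SIM_MODELS,
                         seed: int = 0, level: float = 0.90,
                         n_trees: int = 1000):
    """Replicate the simulation benchmark across cases.

    Returns (rmspe_table, coverage_table, constants_table): RMSPE means with
    standard errors SD/sqrt(n_runs) per case x model, mean interval coverage,
    and the run-averaged calibration constants a and c.
    """
    if cases is None:
        cases = list(CASES.values())
    cases = [CASES[c] if isinstance(c, int) else c for c in cases]
    rmspe_rows, cov_rows, const_rows = [], [], []
    for case in cases:
        per_model = {m: {"rmspe": [], "coverage": []} for m in models}
        a_vals, c_vals = [], []
        n_ok = 0
        for run in range(n_runs):
            try:
                res = simulate_one_run(case, seed, run, models, level, n_trees)
            except Exception as exc:
                logger.warning("case %d run %d failed: %s", case.case_id, run,
                               exc)
                continue
            n_ok += 1
            a_vals.append(res["a"])
            c_vals.append(res["c"])
            for m in models:
                per_model[m]["rmspe"].append(res[m]["rmspe"])
                per_model[m]["coverage"].append(res[m]["coverage"])
        row_r = {"case": case.case_id, "structure": case.label,
                 "r2": case.r2, "nugget": case.nugget,
                 "partial_sill": case.partial_sill, "n_runs": n_ok,
                 "flagged": n_ok < n_runs}
        row_c = dict(row_r)
        for m in models:
            vals = np.asarray(per_model[m]["rmspe"])
            row_r[m] = float(np.mean(vals))
            row_r[f"{m}_se"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            row_c[m] = float(np.mean(per_model[m]["coverage"]))
        rmspe_rows.append(row_r)
        cov_rows.append(row_c)
        const_rows.append({"case": case.case_id,
                           "a": float(np.mean(a_vals)),
                           "c": float(np.mean(c_vals))})
    return (pd.DataFrame(rmspe_rows).set_index("case"),
            pd.DataFrame(cov_rows).set_index("case"),
            pd.DataFrame(const_rows).set_index("case"))


def rank_covariates_slm(fit: SLMResults) -> pd.DataFrame:
    """Covariates ranked by the absolute t-statistics of their coefficients."""
    table = pd.DataFrame({
        "covariate": fit.exog_names,
        "estimate": fit.params,
        "t": fit.tvalues,
        "abs_t": np.abs(fit.tvalues),
    }).sort_values(["abs_t", "covariate"], ascending=[False, True],
                   kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
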