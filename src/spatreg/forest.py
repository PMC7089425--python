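"""Random-forest regression with quantile intervals and regression kriging.

The forest is a bagged ensemble of CART regression trees: each tree is grown
on a bootstrap sample, considering ``mtry`` randomly chosen covariates at
each split, down to terminal nodes of at least ``min_node_size`` cases.
Tree induction is delegated to scikit-learn's ``DecisionTreeRegressor``; the
bagging loop, leaf bookkeeping, out-of-bag indices, quantile-regression-forest
weights, prediction intervals, permutation importance and the
regression-kriging hybrid are implemented here, because they need access to
the per-tree leaf membership of every training observation.

Quantile regression forests (Meinshausen's construction) estimate the full
conditional distribution: each training response receives the weight

    w_i(x0) = (1/B) * sum_b  m_ib(x0) / |leaf_b(x0)|,

where m_ib counts the bootstrap copies of observation i in the leaf that x0
falls into in tree b.  The weighted empirical CDF is inverted left-
continuously, Q_a(x0) = inf{y_i : sum w_i 1{y_i <= y} >= a}, so the forest
mean prediction is exactly the weight-averaged training response.

Random forest regression kriging (RFRK) adds a simple-kriging prediction of
the spatially autocorrelated part of the forest's residual field, and uses
the simple-kriging variance for prediction intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .kriging import PredictionResult, fit_simple_kriging, z_multiplier

__all__ = ["ForestConfig", "RandomForestQuantile", "RFRK"]


@dataclass(frozen=True)
class ForestConfig:
    """Forest tuning parameters (defaults follow common practice for
    environmental data: many trees, mtry = p/3, node size 5).

    ``min_node_size`` uses the classical regression-forest convention: a node
    with at most this many cases becomes terminal; larger nodes keep
    splitting (so children may be smaller).  This grows deeper trees than a
    minimum-leaf-size rule with the same number.
    """

    n_trees: int = 1000
    mtry: int | None = None  # default floor(p/3), at least 1
    min_node_size: int = 5
    seed: int | None = None

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        m = self.mtry if self.mtry is not None else max(1, p // 3)
        if m > p:
            raise ValueError(f"mtry={m} exceeds number of covariates p={p}")
        return m


class RandomForestQuantile:
    """Regression forest with leaf tracking for quantile intervals.

    Parameters mirror :class:`ForestConfig`; a single master seed fans out
    deterministic per-tree bootstrap and split seeds.
    """

    def __init__(self, n_trees: int = 1000, mtry: int | None = None,
                 min_node_size: int = 5, seed: int | None = None):
        self.config = ForestConfig(n_trees, mtry, min_node_size, seed)
        self._fitted = False

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y) -> "RandomForestQuantile":
        X = self._as_matrix(X, fitting=True)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if p == 0:
            raise ValueError("at least one covariate is required")
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("missing or non-finite values in training data")
        cfg = self.config
        mtry = cfg.resolve_mtry(p)
        rng = np.random.default_rng(cfg.seed)
        tree_seeds = rng.integers(0, 2 ** 31 - 1, size=cfg.n_trees)
        self.trees_ = []
        self.bootstrap_idx_ = []
        self.oob_idx_ = []
        self._leaf_tables = []  # per tree: (n_leaves x n) bootstrap-count table
        self._leaf_maps = []    # per tree: raw node id -> dense leaf index
        for b in range(cfg.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeRegressor(
                max_features=mtry, min_samples_split=cfg.min_node_size + 1,
                min_samples_leaf=1, random_state=int(tree_seeds[b]),
            ).fit(X[idx], y[idx])
            leaves_b = tree.apply(X[idx])
            uniq, dense = np.unique(leaves_b, return_inverse=True)
            table = np.zeros((len(uniq), n))
            np.add.at(table, (dense, idx), 1.0)
            table /= table.sum(axis=1, keepdims=True)
            leaf_map = np.full(tree.tree_.node_count, -1, dtype=np.int64)
            leaf_map[uniq] = np.arange(len(uniq))
            self.trees_.append(tree)
            self.bootstrap_idx_.append(idx)
            self.oob_idx_.append(np.setdiff1d(np.arange(n), idx))
            self._leaf_tables.append(table)
            self._leaf_maps.append(leaf_map)
        self.X_, self.y_ = X, y
        self._fitted = True
        return self

    def _as_matrix(self, X, fitting=False):
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_ = [str(c) for c in X.columns]
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if fitting:
                self.feature_names_ = [f"x{j}" for j in range(X.shape[1])]
        return X

    def _check_fitted(self):
        if not self._fitted:
            raise RuntimeError("forest is not fitted")

    # -- prediction ---------------------------------------------------------

    def predict(self, X0) -> np.ndarray:
        """Ensemble mean prediction (average over tree predictions)."""
        self._check_fitted()
        X0 = self._as_matrix(X0)
        out = np.zeros(len(X0))
        for tree in self.trees_:
            out += tree.predict(X0)
        return out / len(self.trees_)

    def weights(self, X0) -> np.ndarray:
        """QRF weight matrix over training rows, shape (m, n); rows sum to 1."""
        self._check_fitted()
        X0 = self._as_matrix(X0)
        W = np.zeros((len(X0), len(self.y_)))
        for tree, table, leaf_map in zip(self.trees_, self._leaf_tables,
                                         self._leaf_maps):
            pos = leaf_map[tree.apply(X0)]
            W += table[pos]
        return W / len(self.trees_)

    def quantile(self, X0, alpha) -> np.ndarray:
        """Weighted-CDF quantile estimate Q_alpha at each row of X0.

        Left-continuous inversion: the smallest training response whose
        cumulative weight reaches alpha.
        """
        alphas = np.atleast_1d(np.asarray(alpha, dtype=float))
        if np.any((alphas <= 0) | (alphas >= 1)):
            raise ValueError("quantile levels must be in (0, 1)")
        W = self.weights(X0)
        order = np.argsort(self.y_, kind="stable")
        y_sorted = self.y_[order]
        cdf = np.cumsum(W[:, order], axis=1)
        out = np.empty((len(W), len(alphas)))
        for j, a in enumerate(alphas):
            pos = np.argmax(cdf >= a - 1e-12, axis=1)
            out[:, j] = y_sorted[pos]
        return out[:, 0] if np.isscalar(alpha) else out

    def interval(self, X0, level: float = 0.90) -> PredictionResult:
        """QRF prediction interval [Q_{(1-level)/2}, Q_{(1+level)/2}]."""
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1)")
        lo_a, hi_a = (1.0 - level) / 2.0, (1.0 + level) / 2.0
        q = self.quantile(X0, np.array([lo_a, hi_a]))
        return PredictionResult(mean=self.predict(X0), se=None,
                                lower=q[:, 0], upper=q[:, 1], level=level)

    # -- diagnostics --------------------------------------------------------

    def oob_prediction(self) -> np.ndarray:
        """Out-of-bag mean prediction per training row (NaN if never OOB)."""
        self._check_fitted()
        n = len(self.y_)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_idx_):
            if len(oob):
                total[oob] += tree.predict(self.X_[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    def permutation_importance(self, seed: int | None = None) -> pd.DataFrame:
        """Mean OOB MSE increase per permuted covariate, descending."""
        self._check_fitted()
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        p = self.X_.shape[1]
        deltas = np.zeros(p)
        counts = np.zeros(p)
        for tree, oob in zip(self.trees_, self.oob_idx_):
            if len(oob) < 2:
                continue
            Xo, yo = self.X_[oob], self.y_[oob]
            base = np.mean((yo - tree.predict(Xo)) ** 2)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(len(oob)), j]
                deltas[j] += np.mean((yo - tree.predict(Xp)) ** 2) - base
                counts[j] += 1
        imp = deltas / np.maximum(counts, 1)
        table = pd.DataFrame({"covariate": self.feature_names_,
                              "importance": imp})
        table = table.sort_values("importance", ascending=False,
                                  kind="stable").reset_index(drop=True)
        table["rank"] = np.arange(1, p + 1)
        return table


class RFRK:
    """Random forest regression kriging.

    Fits a forest to (X, y), then a zero-mean ML simple-kriging model to the
    forest's residual field.  Predictions sum the forest mean and the kriged
    residual; intervals are mean +/- z * sqrt(simple-kriging variance).

    Residuals are taken against the out-of-bag prediction (``oob=True``):
    the in-bag forest prediction partially memorizes each training response,
    so in-bag residuals understate the residual variance and yield a
    simple-kriging sill (and hence intervals) that are far too small.  OOB
    residuals are an honest estimate of the prediction-error field.
    """

    def __init__(self, forest: RandomForestQuantile | None = None, oob: bool = True,
                 **forest_kwargs):
        self.forest = forest or RandomForestQuantile(**forest_kwargs)
        self.oob = oob

    def fit(self, X, y, coords, refit_forest: bool = True) -> "RFRK":
        if refit_forest or not self.forest._fitted:
            self.forest.fit(X, y)
        fitted = self.forest.oob_prediction() if self.oob \
            else self.forest.predict(X)
        fitted = np.where(np.isfinite(fitted), fitted, self.forest.predict(X))
        resid = np.asarray(y, dtype=float).ravel() - fitted
        self.residuals_ = resid
        self.coords_ = np.asarray(coords, dtype=float)
        # degenerate residual field (e.g. perfectly predictable response):
        # kriging contributes nothing and the SK fit is undefined
        self.sk_ = None if np.var(resid) == 0 else \
            fit_simple_kriging(resid, coords, method="ml")
        return self

    @property
    def cov_params_(self):
        return None if self.sk_ is None else self.sk_.cov_params_

    def predict(self, X0, coords0, level: float = 0.90) -> PredictionResult:
        rf_mean = self.forest.predict(X0)
        if self.sk_ is None:
            zeros = np.zeros(len(rf_mean))
            return PredictionResult(mean=rf_mean, se=zeros, lower=rf_mean,
                                    upper=rf_mean, level=level)
        sk = self.sk_.predict(coords0, level=level)
        mean = rf_mean + sk.mean
        z = z_multiplier(level)
        return PredictionResult(mean=mean, se=sk.se, lower=mean - z * sk.se,
                                upper=mean + z * sk.se, level=level)
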