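"""Spatial linear model estimated by maximum likelihood or REML.

The model is

    Y = X beta + z + eps,      Sigma = var(Y) = R + sigma_eps^2 I,

where z is a zero-mean Gaussian process with exponential covariance
(partial sill sigma_z^2, range alpha) and eps is independent noise with
nugget variance sigma_eps^2.  The regression coefficients are profiled out
of the likelihood through their GLS solution, and the three covariance
parameters are optimized numerically on the log scale.  A reduced-rank
(knot-based) covariance may be used during optimization so that only
r x r factorizations are required; with knots equal to the data locations
the reduced-rank likelihood is identical to the full-rank one.

``SpatialLM`` follows the Model/Results convention: construct from arrays or
a DataFrame, call :meth:`SpatialLM.fit`, and use the returned
:class:`SLMResults` for coefficient tables, covariance summaries (effective
range, nugget-to-sill ratio, AIC) and universal-kriging prediction.
An intercept-only design reproduces ordinary kriging; ``exog=None`` gives
the zero-mean model used for simple kriging of residual fields.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .covariance import (
    CovarianceParams,
    DenseSolver,
    ReducedRankSolver,
    as_coords,
    exp_cov,
    full_covariance,
    pairwise_distance,
    reduced_rank_parts,
)
from .kriging import PredictionResult, normal_interval

__all__ = ["SpatialLM", "SLMResults", "gls_beta", "effective_range",
           "nugget_to_sill", "default_knots"]

_LOG2PI = np.log(2.0 * np.pi)


def effective_range(params: CovarianceParams, cutoff: float = 0.01) -> float:
    """Distance beyond which autocorrelation falls below ``cutoff``.

    Solves rho(h) = C(h)/C(0) = cutoff for the exponential model:
    -alpha * log(cutoff * (sigma_z^2 + sigma_eps^2) / sigma_z^2).
    May be non-positive when the nugget-to-sill ratio exceeds 1 - cutoff.
    """
    if params.partial_sill <= 0:
        raise ValueError("effective range undefined when partial sill is zero")
    return -params.range_ * np.log(cutoff * params.sill / params.partial_sill)


def nugget_to_sill(params: CovarianceParams) -> float:
    """Nugget-to-sill ratio sigma_eps^2 / (sigma_z^2 + sigma_eps^2)."""
    return params.nugget / params.sill


def gls_beta(y: np.ndarray, X: np.ndarray, solver, names=None):
    """Generalized least squares: beta = (X' Si X)^-1 X' Si y.

    ``solver`` provides Sigma^-1 products. Returns (beta, beta_cov) with
    beta_cov = (X' Sigma^-1 X)^-1.
    """
    siX = solver.solve(X)
    A = X.T @ siX
    b = siX.T @ y
    rank = np.linalg.matrix_rank(A)
    if rank < X.shape[1]:
        label = ""
        if names is not None:
            # point at columns involved in the rank deficiency
            _, R = np.linalg.qr(X)
            dep = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-10]
            label = f" (dependent columns: {dep})"
        raise np.linalg.LinAlgError(f"design matrix is rank deficient{label}")
    beta_cov = np.linalg.inv(A)
    beta = beta_cov @ b
    return beta, beta_cov


def default_knots(coords: np.ndarray, r: int | None = None, seed: int = 0) -> np.ndarray:
    """Knot locations by k-means on the coordinates (fixed seed)."""
    from sklearn.cluster import KMeans

    pts = as_coords(coords)
    n = len(pts)
    if r is None:
        r = int(min(100, max(1, n // 5)))
    r = min(r, n)
    km = KMeans(n_clusters=r, n_init=4, random_state=seed).fit(pts)
    return km.cluster_centers_


class SpatialLM:
    """Spatial linear model with exponential covariance.

    Parameters
    ----------
    endog : array_like, shape (n,)
        Response vector.
    exog : array_like, shape (n, p), DesignMatrix, or None
        Fixed-effects design.  ``None`` specifies the zero-mean model
        (simple kriging of a residual field).
    coords : array_like, shape (n, 2)
        Planar coordinates (consistent units).
    exog_names : sequence of str, optional
        Column labels; defaults to x0..x{p-1}.
    """

    def __init__(self, endog, exog, coords, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.coords = as_coords(coords)
        n = len(self.endog)
        if len(self.coords) != n:
            raise ValueError("coords and endog length mismatch")
        if not np.all(np.isfinite(self.endog)):
            raise ValueError("endog contains non-finite values")
        if exog is None:
            self.exog = np.empty((n, 0))
            self.exog_names = []
        else:
            names = exog_names
            if hasattr(exog, "values") and hasattr(exog, "names"):  # DesignMatrix
                names = names or list(exog.names)
                exog = exog.values
            elif hasattr(exog, "columns"):  # DataFrame
                names = names or [str(c) for c in exog.columns]
                exog = np.asarray(exog, dtype=float)
            exog = np.asarray(exog, dtype=float)
            if exog.ndim == 1:
                exog = exog[:, None]
            if exog.shape[0] != n:
                raise ValueError("exog and endog length mismatch")
            if not np.all(np.isfinite(exog)):
                raise ValueError("exog contains non-finite values")
            self.exog = exog
            self.exog_names = list(names) if names is not None else [
                f"x{j}" for j in range(exog.shape[1])
            ]
        self.nobs = n
        self._dist = None  # lazy dense distance matrix

    @classmethod
    def from_dataframe(cls, data, response, covariates=None, coords=("x", "y"),
                       add_intercept=True):
        """Build the model from a tidy DataFrame of sites."""
        import pandas as pd

        y = data[response]
        xy = data[list(coords)].to_numpy(dtype=float)
        if covariates is None:
            X, names = None, None
        else:
            X = data[list(covariates)].to_numpy(dtype=float)
            names = list(covariates)
            if add_intercept:
                X = np.column_stack([np.ones(len(X)), X])
                names = ["Intercept"] + names
        return cls(y, X, xy, exog_names=names)

    # -- likelihood ---------------------------------------------------------

    def _distances(self) -> np.ndarray:
        if self._dist is None:
            self._dist = pairwise_distance(self.coords, self.coords)
        return self._dist

    def _solver(self, params: CovarianceParams, rank: str, knots):
        if rank == "full":
            d = self._distances()
            sigma = exp_cov(d, params)
            sigma[np.diag_indices_from(sigma)] = params.sill
            return DenseSolver(sigma)
        if rank == "reduced":
            S, K = reduced_rank_parts(self.coords, knots, params)
            return ReducedRankSolver(S, K, params.nugget)
        raise ValueError(f"unknown rank mode {rank!r}")

    def negloglik(self, params: CovarianceParams, method: str = "ml",
                  rank: str = "full", knots=None) -> float:
        """Profiled negative log-likelihood at the given covariance parameters.

        0.5 { n log 2pi + log|Sigma| + r' Sigma^-1 r + c } with
        r = y - X beta_hat(theta); c = 0 for ML and
        c = -p log 2pi + log|X' Sigma^-1 X| for REML.
        """
        solver = self._solver(params, rank, knots)
        y, X = self.endog, self.exog
        p = X.shape[1]
        if p > 0:
            beta, beta_cov = gls_beta(y, X, solver, self.exog_names)
            resid = y - X @ beta
        else:
            resid = y
        quad = resid @ solver.solve(resid)
        value = self.nobs * _LOG2PI + solver.logdet + quad
        if method.lower() == "reml" and p > 0:
            sign, logdet_xsx = np.linalg.slogdet(np.linalg.inv(beta_cov))
            value += -p * _LOG2PI + logdet_xsx
        elif method.lower() not in ("ml", "reml"):
            raise ValueError(f"unknown method {method!r}")
        return 0.5 * value

    def _start_values(self) -> CovarianceParams:
        y, X = self.endog, self.exog
        if X.shape[1] > 0:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            resid = y
        s2 = float(np.var(resid))
        if s2 <= 0:
            raise ValueError("degenerate data: response has no residual variance")
        d = self._distances()
        rng0 = float(np.max(d)) / 4.0
        if rng0 <= 0:
            rng0 = 1.0
        return CovarianceParams(s2 / 2.0, s2 / 2.0, rng0)

    def fit(self, method: str = "reml", rank: str = "full", knots=None,
            start: CovarianceParams | None = None, tol: float = 1e-6,
            maxiter: int = 2000, restarts: int = 1) -> "SLMResults":
        """Estimate covariance parameters and GLS coefficients.

        The objective is the profiled negative log-likelihood, minimized over
        (log nugget, log partial sill, log range) with Nelder-Mead; one
        restart from perturbed initial values is attempted on failure.
        """
        method = method.lower()
        if rank == "reduced" and knots is None:
            knots = default_knots(self.coords)
        if self.exog.shape[1] >= self.nobs:
            raise ValueError("need n > p to fit the model")
        if np.var(self.endog) == 0:
            raise ValueError("degenerate data: constant response")
        theta0 = start or self._start_values()
        x0 = np.log(np.maximum(theta0.as_array(), 1e-12))

        def objective(logtheta):
            if np.any(logtheta > 50):
                return np.inf
            t = np.exp(logtheta)
            try:
                return self.negloglik(
                    CovarianceParams(t[0], t[1], t[2]), method, rank, knots
                )
            except np.linalg.LinAlgError:
                return np.inf

        best = None
        rng = np.random.default_rng(0)
        for attempt in range(restarts + 1):
            xs = x0 if attempt == 0 else x0 + rng.normal(scale=0.5, size=3)
            res = minimize(
                objective, xs, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": tol, "maxiter": maxiter,
                         "maxfev": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
            if best.success and np.isfinite(best.fun):
                break
        if not np.isfinite(best.fun):
            raise RuntimeError(
                f"SLM optimization failed; best objective {best.fun} at "
                f"log-theta {best.x}"
            )
        t = np.exp(best.x)
        theta = CovarianceParams(t[0], t[1], t[2])
        solver = self._solver(theta, rank, knots)
        p = self.exog.shape[1]
        if p > 0:
            beta, beta_cov = gls_beta(self.endog, self.exog, solver,
                                      self.exog_names)
        else:
            beta, beta_cov = np.empty(0), np.empty((0, 0))
        return SLMResults(
            model=self,
            params=beta,
            beta_cov=beta_cov,
            cov_params_=theta,
            method=method,
            rank_mode=rank,
            knots=None if rank == "full" else np.asarray(knots),
            neg_loglik=float(best.fun),
            converged=bool(best.success),
            solver=solver,
        )


@dataclass
class SLMResults:
    """Fitted spatial linear model.

    Carries the GLS coefficient estimates and their covariance, the fitted
    covariance parameters, likelihood/AIC, and enough state to perform
    universal-kriging prediction at new locations.
    """

    model: SpatialLM
    params: np.ndarray
    beta_cov: np.ndarray
    cov_params_: CovarianceParams
    method: str
    rank_mode: str
    knots: np.ndarray | None
    neg_loglik: float
    converged: bool
    solver: object = field(repr=False)
    _si_resid: np.ndarray | None = field(default=None, repr=False)

    @property
    def exog_names(self):
        return self.model.exog_names

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def k_params(self) -> int:
        """Parameter count: p fixed effects + 3 covariance parameters."""
        return self.model.exog.shape[1] + 3

    @property
    def aic(self) -> float:
        return 2.0 * self.neg_loglik + 2.0 * self.k_params

    @property
    def llf(self) -> float:
        return -self.neg_loglik

    def effective_range(self, cutoff: float = 0.01) -> float:
        return effective_range(self.cov_params_, cutoff)

    @property
    def nugget_to_sill(self) -> float:
        return nugget_to_sill(self.cov_params_)

    # -- prediction ---------------------------------------------------------

    def _resid_solve(self) -> np.ndarray:
        if self._si_resid is None:
            y, X = self.model.endog, self.model.exog
            resid = y - X @ self.params if X.shape[1] else y
            self._si_resid = self.solver.solve(resid)
        return self._si_resid

    def predict(self, new_coords, exog=None, level: float = 0.90,
                chunk_size: int = 20000) -> PredictionResult:
        """Universal-kriging prediction at new locations.

        mean = x0' beta + c0' Sigma^-1 (y - X beta)
        var  = C(s0,s0) - c0' Sigma^-1 c0 + t0' (X' Sigma^-1 X)^-1 t0,
        t0 = x0 - X' Sigma^-1 c0, C(s0,s0) = sigma_z^2 + sigma_eps^2
        (a new site carries its own nugget).  With no fixed effects this is
        simple kriging: the trend-uncertainty term is absent.
        Prediction is chunked so the n x m cross-covariance stays bounded.
        """
        theta = self.cov_params_
        pts = as_coords(new_coords)
        p = self.model.exog.shape[1]
        if p > 0:
            if exog is None:
                raise ValueError("exog required for a model with fixed effects")
            if hasattr(exog, "values") and hasattr(exog, "names"):
                if list(exog.names) != list(self.exog_names):
                    raise ValueError(
                        f"design columns {list(exog.names)} do not match "
                        f"fitted design {list(self.exog_names)}"
                    )
                exog = exog.values
            elif hasattr(exog, "columns"):
                exog = np.asarray(exog[list(self.exog_names)], dtype=float) \
                    if set(self.exog_names) <= set(map(str, exog.columns)) \
                    else np.asarray(exog, dtype=float)
            X0 = np.atleast_2d(np.asarray(exog, dtype=float))
            if X0.shape[1] != p:
                raise ValueError(
                    f"exog has {X0.shape[1]} columns, model expects {p}"
                )
        else:
            X0 = np.empty((len(pts), 0))
        si_resid = self._resid_solve()
        y, X = self.model.endog, self.model.exog
        sill = theta.sill
        means = np.empty(len(pts))
        variances = np.empty(len(pts))
        chunk = max(1, int(chunk_size // max(1, self.model.nobs)))
        for lo in range(0, len(pts), chunk):
            hi = min(lo + chunk, len(pts))
            d0 = pairwise_distance(self.model.coords, pts[lo:hi])
            c0 = exp_cov(d0, theta, same_location_mask=(d0 == 0.0))
            mu = c0.T @ si_resid
            if p > 0:
                mu = mu + X0[lo:hi] @ self.params
            si_c0 = self.solver.solve(c0)
            var = sill - np.einsum("ij,ij->j", c0, si_c0)
            if p > 0:
                t0 = X0[lo:hi].T - X.T @ si_c0
                var = var + np.einsum("ij,ij->j", t0, self.beta_cov @ t0)
            means[lo:hi] = mu
            variances[lo:hi] = var
        if np.min(variances) < -1e-8:
            raise FloatingPointError(
                f"negative kriging variance {np.min(variances):.3e}"
            )
        se = np.sqrt(np.clip(variances, 0.0, None))
        lower, upper = normal_interval(means, se, level)
        return PredictionResult(mean=means, se=se, lower=lower, upper=upper,
                                level=level)

    # -- reporting ----------------------------------------------------------

    def coef_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "t": self.tvalues},
            index=self.exog_names,
        )

    def summary(self) -> str:
        theta = self.cov_params_
        lines = [
            "Spatial linear model (exponential covariance)",
            f"  method: {self.method.upper()}  rank: {self.rank_mode}  "
            f"n: {self.model.nobs}  converged: {self.converged}",
            f"  -loglik: {self.neg_loglik:.4f}  AIC: {self.aic:.4f}  "
            f"k: {self.k_params}",
            f"  nugget: {theta.nugget:.4f}  partial sill: "
            f"{theta.partial_sill:.4f}  range: {theta.range_:.4f}",
            f"  nugget-to-sill: {self.nugget_to_sill:.4f}",
        ]
        try:
            lines.append(f"  effective range (0.01): {self.effective_range():.4f}")
        except ValueError:
            pass
        if len(self.params):
            lines.append(self.coef_table().to_string(float_format="%.4f"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable fit summary."""
        theta = self.cov_params_
        out = {
            "method": self.method,
            "rank_mode": self.rank_mode,
            "converged": self.converged,
            "neg_loglik": self.neg_loglik,
            "aic": self.aic,
            "k_params": self.k_params,
            "cov_params": {
                "nugget": theta.nugget,
                "partial_sill": theta.partial_sill,
                "range": theta.range_,
            },
            "nugget_to_sill": self.nugget_to_sill,
            "coefficients": [
                {"name": n, "estimate": float(b), "se": float(s), "t": float(t)}
                for n, b, s, t in zip(self.exog_names, self.params, self.bse,
                                      self.tvalues)
            ],
        }
        try:
            out["effective_range"] = self.effective_range()
        except ValueError:
            out["effective_range"] = None
        return out

    def plot_semivariogram(self, ax=None, n_bins: int = 15, max_frac: float = 0.5):
        """Empirical semivariogram of the GLS residuals vs the fitted model.

        Bins half the squared residual differences by distance (up to
        ``max_frac`` of the maximum pairwise distance) and overlays the
        fitted exponential semivariance
        gamma(h) = nugget + psill * (1 - exp(-h/range)).
        """
        import matplotlib.pyplot as plt

        from .covariance import pairwise_distance

        y, X = self.model.endog, self.model.exog
        resid = y - X @ self.params if X.shape[1] else y
        d = pairwise_distance(self.model.coords, self.model.coords)
        iu = np.triu_indices(self.model.nobs, k=1)
        dist = d[iu]
        gamma = 0.5 * (resid[:, None] - resid[None, :]) ** 2
        gamma = gamma[iu]
        hmax = max_frac * dist.max()
        edges = np.linspace(0.0, hmax, n_bins + 1)
        centers, means = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (dist >= lo) & (dist < hi)
            if np.any(sel):
                centers.append(0.5 * (lo + hi))
                means.append(float(np.mean(gamma[sel])))
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(centers, means, "o", label="empirical")
        theta = self.cov_params_
        h = np.linspace(0, hmax, 200)
        ax.plot(h, theta.nugget + theta.partial_sill * (1 - np.exp(-h / theta.range_)),
                "-", label="fitted exponential")
        ax.set_xlabel("distance")
        ax.set_ylabel("semivariance")
        ax.legend()
        return ax

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
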