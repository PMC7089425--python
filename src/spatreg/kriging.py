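"""Prediction containers, normal-theory intervals, simple kriging, clamping.

Universal kriging lives on :meth:`spatreg.slm.SLMResults.predict`; this module
provides the shared pieces: the :class:`PredictionResult` container, interval
construction, zero-mean simple kriging of residual fields (used by the
random-forest regression-kriging hybrid), and clamping of predictions to a
bounded response scale (e.g. a 0-100 condition index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["PredictionResult", "normal_interval", "fit_simple_kriging",
           "simple_krige", "clamp_predictions"]

# Printed z multipliers used throughout; other levels fall back to the
# normal quantile.
_Z_BY_LEVEL = {0.90: 1.645, 0.95: 1.960}


@dataclass
class PredictionResult:
    """Point predictions with standard errors and interval bounds."""

    mean: np.ndarray
    se: np.ndarray | None
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        if self.se is not None:
            self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))

    def __len__(self):
        return len(self.mean)

    def to_frame(self):
        import pandas as pd

        data = {"pred": self.mean}
        if self.se is not None:
            data["se"] = self.se
        data["lower"] = self.lower
        data["upper"] = self.upper
        return pd.DataFrame(data)


def z_multiplier(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"interval level must be in (0, 1), got {level}")
    return _Z_BY_LEVEL.get(round(level, 6), norm.ppf(0.5 + level / 2.0))


def normal_interval(mean, se, level: float = 0.90):
    """Symmetric normal interval mean +/- z * se (z = 1.645 at 90%)."""
    mean = np.asarray(mean, dtype=float)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(se)):
        raise ValueError("standard errors must be finite")
    z = z_multiplier(level)
    return mean - z * se, mean + z * se


def fit_simple_kriging(residuals, coords, method: str = "ml", **fit_kwargs):
    """Fit a zero-mean exponential-covariance model to a residual field.

    Simple kriging assumes E[e(s)] = 0, so there is no design matrix; the
    covariance parameters are estimated by ML.  Returns an ``SLMResults``
    whose :meth:`predict` yields mean c0' Sigma^-1 e and variance
    sill - c0' Sigma^-1 c0 (no trend-uncertainty term).
    """
    from .slm import SpatialLM

    return SpatialLM(residuals, None, coords).fit(method=method, **fit_kwargs)


def simple_krige(residuals, coords, new_coords, params=None, level: float = 0.90,
                 fitted=None) -> PredictionResult:
    """Simple-kriging prediction of a zero-mean residual field.

    Either pass fitted ``params`` (CovarianceParams) to krige directly, or a
    pre-fitted result via ``fitted``; with neither, covariance parameters are
    estimated by ML first.
    """
    from .covariance import DenseSolver, full_covariance
    from .slm import SLMResults, SpatialLM

    if fitted is not None:
        return fitted.predict(new_coords, level=level)
    if params is None:
        return fit_simple_kriging(residuals, coords).predict(new_coords,
                                                             level=level)
    model = SpatialLM(residuals, None, coords)
    solver = DenseSolver(full_covariance(model.coords, params))
    res = SLMResults(
        model=model, params=np.empty(0), beta_cov=np.empty((0, 0)),
        cov_params_=params, method="fixed", rank_mode="full", knots=None,
        neg_loglik=model.negloglik(params, "ml"), converged=True,
        solver=solver,
    )
    return res.predict(new_coords, level=level)


def clamp_predictions(values, lower_bound: float, upper_bound: float):
    """Truncate predictions into [lower_bound, upper_bound].

    Returns (clamped values, number of entries changed).  Used for bounded
    indices where a linear model can extrapolate outside the response scale.
    """
    if lower_bound > upper_bound:
        raise ValueError("bounds must be ordered")
    values = np.asarray(values, dtype=float)
    clamped = np.clip(values, lower_bound, upper_bound)
    return clamped, int(np.sum(clamped != values))
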