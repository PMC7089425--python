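"""Exponential covariance structures for geostatistical models.

This module holds the numerical core shared by the spatial linear model and
the residual-kriging machinery: pairwise Euclidean distances, the exponential
covariance function with a nugget effect, dense covariance construction, and
the reduced-rank (knot-based) representation whose inverse and log-determinant
are obtained through the Sherman-Morrison-Woodbury identity so that only
r x r factorizations are ever performed.

The covariance model is stationary and isotropic:

    C(u, v) = sigma_z^2 * exp(-||u - v|| / alpha) + 1{u = v} * sigma_eps^2

with partial sill ``sigma_z^2``, range ``alpha`` and nugget ``sigma_eps^2``.
Distances are planar Euclidean; geographic coordinates must be projected
(e.g. to an equal-area CRS in km) before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

__all__ = [
    "CovarianceParams",
    "as_coords",
    "pairwise_distance",
    "exp_cov",
    "full_covariance",
    "reduced_rank_parts",
    "smw_solve_and_logdet",
    "DenseSolver",
    "ReducedRankSolver",
]


@dataclass(frozen=True)
class CovarianceParams:
    """Parameters of the exponential covariance model.

    Parameters
    ----------
    nugget : float
        Micro-scale / measurement-error variance sigma_eps^2 (>= 0).
    partial_sill : float
        Variance sigma_z^2 of the spatially autocorrelated process (>= 0).
    range_ : float
        Distance scale alpha of the exponential decay (> 0).
    """

    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self) -> None:
        vals = (self.nugget, self.partial_sill, self.range_)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("covariance parameters must be finite")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.range_ <= 0:
            raise ValueError(f"range must be strictly positive, got {self.range_}")
        if self.nugget + self.partial_sill <= 0:
            raise ValueError("total sill (nugget + partial sill) must be positive")

    @property
    def sill(self) -> float:
        """Total sill sigma_z^2 + sigma_eps^2."""
        return self.nugget + self.partial_sill

    def as_array(self) -> np.ndarray:
        return np.array([self.nugget, self.partial_sill, self.range_])


def as_coords(points) -> np.ndarray:
    """Validate and return an n x 2 array of planar coordinates."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 2:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"coordinates must be n x 2, got shape {pts.shape}")
    if pts.shape[0] < 1:
        raise ValueError("need at least one coordinate")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates contain non-finite values")
    return pts


def pairwise_distance(a, b) -> np.ndarray:
    """Euclidean distance matrix between two coordinate sets."""
    return cdist(as_coords(a), as_coords(b))


def exp_cov(d: np.ndarray, params: CovarianceParams,
            same_location_mask: np.ndarray | None = None) -> np.ndarray:
    """Exponential covariance evaluated on a distance matrix.

    The nugget is added exactly where ``same_location_mask`` is True
    (coincident locations), matching C(u, u) = sill.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    c = params.partial_sill * np.exp(-d / params.range_)
    if same_location_mask is not None:
        mask = np.asarray(same_location_mask, dtype=bool)
        if mask.shape != d.shape:
            raise ValueError("same_location_mask shape mismatch")
        c = c + params.nugget * mask
    return c


def full_covariance(coords, params: CovarianceParams) -> np.ndarray:
    """Dense n x n covariance matrix Sigma = R + sigma_eps^2 I."""
    pts = as_coords(coords)
    d = pairwise_distance(pts, pts)
    sigma = exp_cov(d, params)
    np.fill_diagonal(sigma, params.sill)
    if params.nugget == 0:
        off = d + np.eye(len(pts))
        if np.any(off == 0):
            import warnings

            warnings.warn(
                "duplicated coordinates with zero nugget yield a singular "
                "covariance matrix",
                RuntimeWarning,
                stacklevel=2,
            )
    return sigma


def reduced_rank_parts(coords, knots, params: CovarianceParams):
    """Knot-based covariance factors (S, K).

    S is n x r with entries sigma_z^2 exp(-||s_i - k_j|| / alpha); K is the
    r x r knot covariance. When the knots equal the data locations,
    S = K = R and the reduced-rank covariance S K^-1 S' + nugget*I coincides
    with the full-rank matrix.
    """
    if params.partial_sill == 0:
        raise ValueError(
            "partial sill is zero: knot covariance K is degenerate; "
            "fall back to the independence model"
        )
    pts = as_coords(coords)
    kts = as_coords(knots)
    if len(np.unique(kts, axis=0)) != len(kts):
        raise ValueError("duplicated knot locations")
    S = params.partial_sill * np.exp(-pairwise_distance(pts, kts) / params.range_)
    K = params.partial_sill * np.exp(-pairwise_distance(kts, kts) / params.range_)
    return S, K


class DenseSolver:
    """Cholesky-backed solves and log-determinant for a dense covariance."""

    def __init__(self, sigma: np.ndarray):
        self.n = sigma.shape[0]
        try:
            self._cho = cho_factor(sigma, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"covariance matrix not positive definite: {exc}"
            ) from exc
        self.logdet = 2.0 * np.sum(np.log(np.diag(self._cho[0])))

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve(self._cho, rhs)


class ReducedRankSolver:
    """Sherman-Morrison-Woodbury solves for Sigma = S K^-1 S' + nugget*I.

    The inverse is sigma_eps^-2 [I - S (sigma_eps^2 K + S'S)^-1 S'] and the
    log-determinant follows from the matrix determinant lemma:

        log|Sigma| = n log sigma_eps^2 + log|K + sigma_eps^-2 S'S| - log|K|.

    Only r x r factorizations are performed.
    """

    _COND_MAX = 1e12

    def __init__(self, S: np.ndarray, K: np.ndarray, nugget: float):
        if nugget <= 0:
            raise ValueError("reduced-rank solver requires a positive nugget")
        self.S = np.asarray(S, dtype=float)
        self.n = self.S.shape[0]
        self.nugget = float(nugget)
        K = np.asarray(K, dtype=float)
        inner = nugget * K + self.S.T @ self.S
        cond = np.linalg.cond(inner)
        if not np.isfinite(cond) or cond > self._COND_MAX:
            raise np.linalg.LinAlgError(
                f"ill-conditioned SMW inner matrix (condition number {cond:.3e})"
            )
        self._inner_cho = cho_factor(inner, lower=True)
        K_cho = cho_factor(K, lower=True)
        logdet_K = 2.0 * np.sum(np.log(np.diag(K_cho[0])))
        # |K + nugget^-1 S'S| = |nugget*K + S'S| / nugget^r
        r = K.shape[0]
        logdet_inner = 2.0 * np.sum(np.log(np.diag(self._inner_cho[0])))
        self.logdet = (
            self.n * np.log(nugget) + logdet_inner - r * np.log(nugget) - logdet_K
        )

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs = np.asarray(rhs, dtype=float)
        tmp = cho_solve(self._inner_cho, self.S.T @ rhs)
        return (rhs - self.S @ tmp) / self.nugget


def smw_solve_and_logdet(S, K, nugget, rhs):
    """One-shot SMW solve: returns (Sigma^-1 @ rhs, log|Sigma|)."""
    solver = ReducedRankSolver(S, K, nugget)
    return solver.solve(rhs), solver.logdet
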