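"""Linear-kernel Gaussian-process regression for wide feature matrices.

With the linear ("vanilla") kernel k(x, x') = x . x', GP regression is
Bayesian linear regression in disguise: the predictive mean is the ridge
solution, but the model is fitted in the dual (Gram) form, which costs
O(n^3) in the number of subjects instead of O(p^3) in the number of
voxels.  For neuroimaging problems with n ~ 16 subjects and p ~ 30 000
voxels this is the only practical route.

Model
-----
Training targets are centred by their mean ``ybar``; the dual
coefficients solve

    (K + sigma2 * I) alpha = y - ybar,      K = X X^T

and the predictive mean at rows ``X_new`` is ``ybar + X_new X^T alpha``.
The equivalent primal (voxel-space) weight vector is ``w = X^T alpha``,
which is what weight maps visualise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "LinearGPRegressor",
    "LinearGPModel",
    "compute_gram",
    "fit_gp",
    "predict_gp",
    "primal_weights",
    "log_marginal_likelihood",
    "optimize_noise",
]


def compute_gram(X: np.ndarray) -> np.ndarray:
    """Linear-kernel Gram matrix K = X X^T.

    Symmetrised explicitly so downstream Cholesky factorisations never
    see floating-point asymmetry.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D (n_subjects, n_features) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    K = X @ X.T
    return (K + K.T) / 2.0


def _solve_spd(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve A x = b for symmetric positive-definite A via Cholesky.

    Returns (x, cho_factor).  On factorisation failure a single jitter of
    1e-10 * trace(A)/n is added (logged as a warning); if that also fails
    the matrix is genuinely singular and an error propagates.
    """
    try:
        c = linalg.cho_factor(A, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.trace(A) / A.shape[0]
        if jitter <= 0:
            jitter = 1e-12
        logger.warning(
            "Gram factorization failed; retrying with jitter %.3e", jitter
        )
        c = linalg.cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
    return linalg.cho_solve(c, b), c


class LinearGPRegressor:
    """Gaussian-process regressor with a linear kernel, fitted in the dual.

    Parameters
    ----------
    sigma2 : float, default 0.001
        Observation-noise variance added to the Gram diagonal.  The
        default replicates the conventional small fixed value used for
        global-mean-scaled, age-residualised PET features.
    optimize_sigma2 : bool, default False
        If True, ``sigma2`` is treated as the initial value and the noise
        variance is tuned by type-II maximum likelihood (bounded 1-D
        search over log sigma2) before the final solve.
    bounds : (float, float), default (1e-6, 1e3)
        Search bounds for the noise variance when optimising.
    tol : float, default 0.001
        Termination tolerance of the noise-variance search.

    Attributes (set by :meth:`fit`)
    -------------------------------
    X_train_ : (n, p) array — training features.
    gram_ : (n, n) array — K = X X^T.
    alpha_ : (n,) array — dual coefficients.
    y_mean_ : float — training-target mean.
    sigma2_ : float — noise variance actually used.
    coef_ : (p,) array — primal weights X^T alpha.

    The class follows the scikit-learn estimator protocol
    (``get_params`` / ``set_params`` / ``fit`` / ``predict``) without
    depending on scikit-learn.
    """

    def __init__(
        self,
        sigma2: float = 0.001,
        optimize_sigma2: bool = False,
        bounds: tuple[float, float] = (1e-6, 1e3),
        tol: float = 0.001,
    ):
        self.sigma2 = sigma2
        self.optimize_sigma2 = optimize_sigma2
        self.bounds = bounds
        self.tol = tol

    # -- sklearn protocol -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "sigma2": self.sigma2,
            "optimize_sigma2": self.optimize_sigma2,
            "bounds": self.bounds,
            "tol": self.tol,
        }

    def set_params(self, **params) -> "LinearGPRegressor":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- estimator API ----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearGPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = X.shape[0]
        if y.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if n < 2:
            raise ValueError("need at least 2 training subjects")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

        K = compute_gram(X)
        sigma2 = float(self.sigma2)
        if self.optimize_sigma2:
            sigma2 = optimize_noise(X, y, bounds=self.bounds, tol=self.tol, gram=K)

        resid = y - y.mean()
        A = K + sigma2 * np.eye(n)
        if sigma2 == 0.0:
            # interpolation regime: K must be invertible
            if np.linalg.matrix_rank(K) < n:
                raise linalg.LinAlgError(
                    "sigma2 = 0 with a rank-deficient Gram matrix"
                )
        alpha, _ = _solve_spd(A, resid)

        self.X_train_ = X
        self.gram_ = K
        self.alpha_ = alpha
        self.y_mean_ = float(y.mean())
        self.sigma2_ = sigma2
        self.coef_ = X.T @ alpha
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.X_train_.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model has "
                f"{self.X_train_.shape[1]}, got {X.shape[1]}"
            )
        return self.y_mean_ + (X @ self.X_train_.T) @ self.alpha_

    def _check_fitted(self) -> None:
        if not hasattr(self, "alpha_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


@dataclass
class LinearGPModel:
    """Fitted linear-kernel GP in dual form (functional API)."""

    X_train: np.ndarray
    alpha: np.ndarray
    sigma2: float
    y_mean: float
    gram: np.ndarray


def fit_gp(X: np.ndarray, y: np.ndarray, sigma2: float = 0.001) -> LinearGPModel:
    """Fit a linear-kernel GP; thin wrapper over :class:`LinearGPRegressor`."""
    est = LinearGPRegressor(sigma2=sigma2).fit(X, y)
    return LinearGPModel(
        X_train=est.X_train_,
        alpha=est.alpha_,
        sigma2=est.sigma2_,
        y_mean=est.y_mean_,
        gram=est.gram_,
    )


def predict_gp(model: LinearGPModel, X_new: np.ndarray) -> np.ndarray:
    """Predictive mean ybar + K(X_new, X_train) alpha."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError("feature dimension mismatch")
    return model.y_mean + (X_new @ model.X_train.T) @ model.alpha


def primal_weights(model: LinearGPModel) -> np.ndarray:
    """Voxel-space weight vector w = X^T alpha.

    Satisfies ybar + X_new w == predict_gp(model, X_new) exactly (up to
    floating point); this is the quantity weight maps display.
    """
    return model.X_train.T @ model.alpha


def log_marginal_likelihood(
    X: np.ndarray,
    y: np.ndarray,
    sigma2: float,
    gram: np.ndarray | None = None,
) -> float:
    """Log evidence of the centred targets under the linear-kernel GP.

    -1/2 r^T (K + s2 I)^-1 r - 1/2 log det(K + s2 I) - n/2 log 2pi,
    with r = y - mean(y), computed through a Cholesky factorisation
    (never an explicit inverse or determinant).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    K = compute_gram(X) if gram is None else gram
    resid = y - y.mean()
    A = K + sigma2 * np.eye(n)
    alpha, c = _solve_spd(A, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return float(-0.5 * resid @ alpha - 0.5 * logdet - 0.5 * n * math.log(2 * math.pi))


def optimize_noise(
    X: np.ndarray,
    y: np.ndarray,
    bounds: tuple[float, float] = (1e-6, 1e3),
    tol: float = 0.001,
    gram: np.ndarray | None = None,
) -> float:
    """Type-II maximum-likelihood noise variance.

    Bounded scalar maximisation of the log marginal likelihood over
    log(sigma2); deterministic (no multistart).  ``tol`` bounds the
    uncertainty of the returned sigma2.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    if tol <= 0:
        raise ValueError("tol must be positive")
    K = compute_gram(X) if gram is None else gram

    def neg_evidence(log_s2: float) -> float:
        return -log_marginal_likelihood(X, y, math.exp(log_s2), gram=K)

    # xatol on the log scale: exp(log s2 +- xatol) moves sigma2 by about
    # sigma2 * xatol, so tol/hi is conservative; floor avoids silly precision.
    xatol = max(min(tol, tol / hi), 1e-10)
    res = optimize.minimize_scalar(
        neg_evidence,
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": xatol},
    )
    # a boundary optimum can leave the bounded search a hair inside the
    # bracket; return whichever of {interior solution, endpoints} wins
    candidates = [math.log(lo), res.x, math.log(hi)]
    best = min(candidates, key=neg_evidence)
    return float(math.exp(best))
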