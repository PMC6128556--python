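"""PCA of a neuropsychological battery.

A battery of correlated cognitive tests (17 measures here) is summarised
by the principal components of the centred-and-scaled score matrix; the
leading components are then used as prediction targets.  Variance
fractions populate the scree plot, and squared loadings (x100) give each
measure's percentage contribution to a component, against an expected
average of 100/p.

Implemented directly via the singular value decomposition of the
standardized matrix (sample, n-1, variance convention).  Timing-based
measures that are right-skewed (e.g. pegboard completion times) can be
log-transformed first; because a logarithm base change only rescales a
column, and every column is subsequently z-scored, downstream results do
not depend on the base (base 10 used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "BatteryPCA",
    "log_transform",
    "standardize",
    "pca",
    "contributions",
    "cumulative_variance",
]


@dataclass
class PCAResult:
    """Loadings, scores, variance fractions and contributions.

    loadings : (p, k) orthonormal columns (principal axes).
    scores : (n, k) component scores (standardized data x loadings).
    variance_fractions : (k,) descending, summing to 1 over the full rank.
    contributions : (p, k) percentages; each column sums to 100.
    measure_names : column labels carried through for reporting.
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_fractions: np.ndarray
    contributions: np.ndarray
    measure_names: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def log_transform(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Replace the named columns by their base-10 logarithm.

    Rejects non-positive values, identifying the offending cell, since a
    log transform of a timing score is only meaningful for positive times.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"no such column {col!r}")
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            row = int(np.argmax(vals <= 0))
            raise ValueError(
                f"log transform of column {col!r} requires positive values; "
                f"row {row} has {vals[row]!r}"
            )
        out[col] = np.log10(vals)
    return out


def standardize(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Centre and scale each column to mean 0, sample SD 1 (n-1 denominator)."""
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D table")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"column {bad} has zero variance; cannot standardize")
    return (X - X.mean(axis=0)) / sd


def pca(Z: np.ndarray, measure_names: list[str] | None = None) -> PCAResult:
    """Principal components of a standardized matrix via SVD.

    Components are ordered by decreasing variance; the number retained is
    min(n-1, p) (a centred n-row matrix has rank at most n-1).  Sign
    convention: each loading column is flipped so its largest-magnitude
    entry is positive, making results deterministic.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    k = min(n - 1, p)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:k].T
    # deterministic sign: largest-|entry| of each column made positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    eigvals = S[:k] ** 2 / (n - 1)
    fractions = eigvals / eigvals.sum()
    scores = Z @ loadings
    contrib = 100.0 * loadings**2
    if measure_names is None:
        measure_names = [f"m{j:02d}" for j in range(p)]
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_fractions=fractions,
        contributions=contrib,
        measure_names=list(measure_names),
    )


def contributions(result: PCAResult, component: int) -> np.ndarray:
    """Per-measure percentage contributions to one component (1-based).

    100 x squared loading; sums to 100 because loading columns are
    unit-norm.  The scree-companion reference line is 100 / p.
    """
    if not 1 <= component <= result.n_components:
        raise IndexError(f"component {component} out of range")
    return result.contributions[:, component - 1]


def cumulative_variance(result: PCAResult, k: int) -> float:
    """Fraction of variance explained by the first k components."""
    if not 1 <= k <= result.n_components:
        raise IndexError(f"k={k} out of range")
    return float(result.variance_fractions[:k].sum())


class BatteryPCA:
    """Estimator bundling log transform, standardization and PCA.

    Parameters
    ----------
    log_columns : list of column names to log10-transform before scaling.

    After :meth:`fit`, exposes ``result_`` (:class:`PCAResult`) plus the
    column means/SDs used for standardization (``mean_``, ``scale_``).
    ``transform`` projects new, identically-coded tables onto the fitted
    axes.
    """

    def __init__(self, log_columns: list[str] | None = None):
        self.log_columns = log_columns

    def get_params(self, deep: bool = True) -> dict:
        return {"log_columns": self.log_columns}

    def set_params(self, **params) -> "BatteryPCA":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _prepare(self, table: pd.DataFrame) -> np.ndarray:
        if self.log_columns:
            table = log_transform(table, self.log_columns)
        return table.to_numpy(dtype=float)

    def fit(self, table: pd.DataFrame) -> "BatteryPCA":
        X = self._prepare(table)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("zero-variance column; cannot standardize")
        Z = (X - self.mean_) / self.scale_
        self.result_ = pca(Z, measure_names=list(table.columns))
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("not fitted")
        X = self._prepare(table)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.result_.loadings

    def fit_transform(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).result_.scores
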