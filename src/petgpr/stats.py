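"""Two-group demographic and neuropsychological comparisons.

Student's pooled-variance t-test, Cohen's d (pooled-SD definition) and a
2x2 Pearson chi-square, computable either from raw per-subject tables or
directly from published summary statistics (mean, SD, n per group) — the
latter lets a reported patient-vs-control comparison table be recomputed
without access to the raw scores.

A reference summary table from a published NF1-versus-control battery
comparison (16 subjects per group, 17 cognitive measures plus
demographics) ships with the package as ``data/nf1_group_summary.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pca import log_transform

__all__ = [
    "SummaryRow",
    "ComparisonResult",
    "pooled_t_from_summary",
    "cohens_d_pooled",
    "chi_square_2x2",
    "compare_summary",
    "compare_groups",
    "load_reference_summary",
]


@dataclass
class SummaryRow:
    """Per-measure summary statistics for two groups."""

    measure: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def __post_init__(self):
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")


@dataclass
class ComparisonResult:
    measure: str
    t: float
    df: int
    p: float
    cohens_d: float


def _pooled_sd(row: SummaryRow) -> float:
    s2 = ((row.n1 - 1) * row.sd1**2 + (row.n2 - 1) * row.sd2**2) / (
        row.n1 + row.n2 - 2
    )
    return float(np.sqrt(s2))


def pooled_t_from_summary(row: SummaryRow) -> ComparisonResult:
    """Student's two-sample t-test (pooled variance) from summary stats.

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)), df = n1 + n2 - 2,
    two-tailed p.  Welch's variant is deliberately not the default: the
    pooled test is what "Student t-test" denotes for matched group sizes.
    """
    sp = _pooled_sd(row)
    if sp == 0:
        raise ValueError("zero pooled variance")
    df = row.n1 + row.n2 - 2
    t = (row.mean1 - row.mean2) / (sp * np.sqrt(1 / row.n1 + 1 / row.n2))
    p = float(2 * sps.t.sf(abs(t), df))
    return ComparisonResult(
        measure=row.measure, t=float(t), df=df, p=p,
        cohens_d=cohens_d_pooled(row),
    )


def cohens_d_pooled(row: SummaryRow) -> float:
    """Cohen's d with the pooled SD; sign follows mean1 - mean2."""
    sp = _pooled_sd(row)
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    return float((row.mean1 - row.mean2) / sp)


def chi_square_2x2(counts, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 contingency table.

    Continuity correction off by default (``yates=True`` enables it).
    Returns (chi2, df=1, p).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("empty table")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("a zero marginal makes the test undefined")
    expected = np.outer(row, col) / counts.sum()
    diff = np.abs(counts - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, 1))
    return chi2, 1, p


def compare_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Run the pooled t-test + Cohen's d over a whole summary table.

    Expects columns measure, mean1, sd1, n1, mean2, sd2, n2; returns one
    row per measure with t, df, p, cohens_d.
    """
    results = []
    for rec in summary.itertuples(index=False):
        row = SummaryRow(
            measure=str(rec.measure),
            mean1=float(rec.mean1), sd1=float(rec.sd1), n1=int(rec.n1),
            mean2=float(rec.mean2), sd2=float(rec.sd2), n2=int(rec.n2),
        )
        r = pooled_t_from_summary(row)
        results.append(vars(r))
    return pd.DataFrame(results)


def compare_groups(
    group1: pd.DataFrame,
    group2: pd.DataFrame,
    log_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group comparison from raw per-subject tables.

    Applies the log transform to the named (timing) columns first, then
    computes per-measure means/SDs and delegates to the summary path, so
    raw and summary routes agree exactly on the same data.  Non-numeric
    columns (e.g. subject_id) are ignored.
    """
    if log_columns:
        group1 = log_transform(group1, log_columns)
        group2 = log_transform(group2, log_columns)
    num1 = group1.select_dtypes("number")
    num2 = group2.select_dtypes("number")
    if list(num1.columns) != list(num2.columns):
        raise ValueError("groups have mismatched measure sets")
    summary = pd.DataFrame(
        {
            "measure": num1.columns,
            "mean1": num1.mean().to_numpy(),
            "sd1": num1.std(ddof=1).to_numpy(),
            "n1": len(num1),
            "mean2": num2.mean().to_numpy(),
            "sd2": num2.std(ddof=1).to_numpy(),
            "n2": len(num2),
        }
    )
    return compare_summary(summary)


def load_reference_summary() -> pd.DataFrame:
    """Published NF1-vs-control summary table (control = group 1).

    Means and SDs as printed in the source report (the two pegboard rows
    are on the log scale there); recomputing pooled t-tests from these
    reproduces the published p-values to their 3-decimal rounding.
    """
    with resources.files("petgpr").joinpath(
        "data/nf1_group_summary.csv"
    ).open() as fh:
        return pd.read_csv(fh)
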