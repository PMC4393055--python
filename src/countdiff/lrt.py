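"""Poisson likelihood-ratio tests for count homogeneity and differential expression.

Model: the read count of a gene in replicate j is Poisson with mean λ_j
(counts are a small fraction of the lane total, so the Poisson limit of the
binomial applies). Two likelihood ratios are used:

* **Within a condition** — H0: λ_1 = … = λ_m against any inequality. With
  pooled count x = Σ x_j the ratio is Λ = x^x / (m^x ∏ x_j^{x_j}); small
  values reject. This screens technical replicates for reproducibility.
* **Between conditions** — pooled counts x ~ Poisson(mλ), y ~ Poisson(nμ),
  H0: λ = μ. The ratio is Λ = (m/(m+n))^x (n/(m+n))^y (x+y)^{x+y}/(x^x y^y).

Calibration uses Wilks' asymptotics: −2 log Λ is referred to a chi-square
with m−1 (within) or 1 (between) degrees of freedom. The convention
0·log 0 = 0 makes log Λ continuous at zero counts, so all-zero genes give
Λ = 1 and p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .count_io import RESULT_COLUMNS, CountMatrix, ResultTable
from .errors import MappingError

__all__ = [
    "ReplicateVector",
    "LRTResult",
    "log_lambda_within",
    "log_lambda3_between",
    "within_screen",
    "within_screen_summary",
    "de_lrt",
]


@dataclass
class ReplicateVector:
    """One gene's counts across the technical replicates of one condition."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("need a 1-D vector with at least one replicate")
        if (self.counts < 0).any() or not np.all(np.mod(self.counts, 1) == 0):
            raise ValueError("replicate counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)

    @property
    def m(self) -> int:
        return self.counts.size


@dataclass
class LRTResult:
    log_statistic: float  # log Λ, always ≤ 0
    df: int
    p_value: float
    reject: bool
    level: float


def _ratio_terms(weights, numer, denom):
    """Σ w·log(numer/denom) over entries with w > 0 (0·log 0 = 0).

    Written as a log of a ratio, not a difference of logs, so the term is
    exactly 0.0 when numerator and denominator are equal — equal-sample-mean
    inputs give log Λ = 0 with no floating-point residue.
    """
    w = np.asarray(weights, dtype=float)
    num = np.asarray(numer, dtype=float)
    den = np.asarray(denom, dtype=float)
    safe = np.where(w > 0, den, 1.0)
    return np.where(w > 0, w * np.log(np.where(w > 0, num, 1.0) / safe), 0.0)


def _result(log_lam: float, df: int, level: float) -> LRTResult:
    log_lam = min(float(log_lam), 0.0)  # clip float noise; Λ ≤ 1 always
    p = float(chi2.sf(-2.0 * log_lam, df))
    return LRTResult(log_lam, df, p, p <= level, level)


def log_lambda_within(reps: ReplicateVector | np.ndarray, level: float = 0.05) -> LRTResult:
    """Within-condition homogeneity LRT on one gene's replicate counts.

    Requires m ≥ 2 replicates. log Λ = x log x − x log m − Σ_j x_j log x_j,
    df = m − 1, p-value from the chi-square upper tail at −2 log Λ.
    """
    if not isinstance(reps, ReplicateVector):
        reps = ReplicateVector(np.asarray(reps))
    if reps.m < 2:
        raise ValueError("within-condition test needs at least 2 replicates")
    x = int(reps.counts.sum())
    # log Λ1 = Σ_j x_j log(x / (m x_j)); identical replicates give exactly 0
    log_lam = _ratio_terms(reps.counts, x, reps.m * reps.counts).sum()
    return _result(log_lam, reps.m - 1, level)


def log_lambda3_between(
    x: int, m: int, y: int, n: int, level: float = 0.05
) -> LRTResult:
    """Two-condition LRT on pooled counts x (m replicates) vs y (n replicates)."""
    if m < 1 or n < 1:
        raise ValueError("replicate numbers m, n must be positive")
    if x < 0 or y < 0:
        raise ValueError("pooled counts must be non-negative")
    # log Λ3 = x log(m(x+y)/((m+n)x)) + y log(n(x+y)/((m+n)y)); exactly 0 at x/m = y/n
    log_lam = float(
        _ratio_terms(x, m * (x + y), (m + n) * x)
        + _ratio_terms(y, n * (x + y), (m + n) * y)
    )
    return _result(log_lam, 1, level)


def _within_pvalues(cm: CountMatrix, condition: str) -> tuple[np.ndarray, np.ndarray, int]:
    counts = cm.submatrix(condition)
    m = counts.shape[1]
    if m < 2:
        raise MappingError(f"condition {condition!r} has fewer than 2 lanes")
    x = counts.sum(axis=1)
    log_lam = np.minimum(_ratio_terms(counts, x[:, None], m * counts).sum(axis=1), 0.0)
    return chi2.sf(-2.0 * log_lam, m - 1), log_lam, m


def within_screen(
    cm: CountMatrix, condition: str, level: float = 0.05
) -> tuple[list[LRTResult], float]:
    """Per-gene homogeneity tests for one condition's lanes.

    Returns the per-gene results and the percentage of genes whose counts
    are similar across replicates (p > level), the reproducibility summary.
    """
    p, log_lam, m = _within_pvalues(cm, condition)
    results = [
        LRTResult(float(ll), m - 1, float(pv), pv <= level, level)
        for ll, pv in zip(log_lam, p)
    ]
    pct = 100.0 * float(np.mean(p > level)) if p.size else 100.0
    return results, pct


def within_screen_summary(
    cm: CountMatrix,
    condition: str,
    levels: tuple[float, ...] = (0.01, 0.025, 0.05, 0.10),
) -> dict[float, float]:
    """Percentage of replicate-consistent genes at each significance level."""
    p, _, _ = _within_pvalues(cm, condition)
    return {lvl: 100.0 * float(np.mean(p > lvl)) for lvl in levels}


def de_lrt(cm: CountMatrix, level: float = 0.01) -> ResultTable:
    """Two-condition LRT applied gene-by-gene on pooled per-condition counts.

    Every gene is tested (no presence filtering — see the workflow module
    for the categorized pipeline); genes with zero counts everywhere give
    Λ = 1, p = 1 by the 0·log 0 convention.
    """
    from .workflow import fold_change  # deferred: workflow orchestrates this module

    labels = cm.condition_labels
    if len(labels) != 2:
        raise MappingError("two-condition test needs exactly two conditions")
    c1, c2 = labels
    m, n = len(cm.lanes_of(c1)), len(cm.lanes_of(c2))
    x = cm.pooled(c1)
    y = cm.pooled(c2)
    log_lam = np.minimum(
        _ratio_terms(x, m * (x + y), (m + n) * x)
        + _ratio_terms(y, n * (x + y), (m + n) * y),
        0.0,
    )
    p = chi2.sf(-2.0 * log_lam, 1)
    df = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "category": 3,
            "x_pooled": x.astype(np.int64),
            "y_pooled": y.astype(np.int64),
            "statistic": -2.0 * log_lam,
            "p_value": p,
            "interval_low": np.nan,
            "interval_high": np.nan,
            "log2_fold": [fold_change(xi, m, yi, n) for xi, yi in zip(x, y)],
            "de": p <= level,
            "status": "tested",
        },
        columns=RESULT_COLUMNS,
    )
    return ResultTable(df)
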