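"""Generalized Audic–Claverie predictive test for count reproducibility and DE.

A gene's count in one replicate is Poisson with unknown mean λ. Placing a
flat prior on λ and integrating it out, the law of a new replicate's count
X given a pooled count s observed in the other m − 1 replicates is

    P(X = x | s) = C(s + x, x) · ((m−1)/m)^{s+1} · (1/m)^x,

a negative binomial with size s + 1 and success probability (m−1)/m — the
m = 2 case is the classical Audic–Claverie law, and chaining conditionals
extends it to any number of replicates. An acceptance interval [a, b] with
per-tail mass α is cut from this law: a is the smallest integer whose
cumulative mass reaches α and b the largest integer whose upper-tail mass
is still at least α, so the inclusive interval always carries at least
1 − 2α of the predictive mass.

Uses: a leave-one-out sweep flags technical replicates inconsistent with
the rest (``within_consistency``); with equal replicate numbers m = n the
pooled counts of two conditions are treated as two replicates of one law,
and a condition-2 pooled count outside the interval built from condition-1
is called differentially expressed (``de_bayes``).

All factorial arithmetic is in log space via log-gamma; tail sums use the
regularized incomplete-beta form of the negative-binomial CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom

from .errors import UnequalReplicatesError

__all__ = [
    "PredictiveLaw",
    "AcceptanceInterval",
    "log_predictive_pmf",
    "acceptance_interval",
    "within_consistency",
    "de_bayes",
]


@dataclass(frozen=True)
class PredictiveLaw:
    """Predictive law of one replicate given the others.

    ``s`` is the pooled count over the m − 1 conditioning replicates and
    ``m`` the total replicate number including the predicted one.
    """

    s: int
    m: int

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("pooled prior count s must be non-negative")
        if self.m < 2:
            raise ValueError("predictive law needs at least m = 2 replicates")

    def frozen(self):
        """scipy negative-binomial equivalent (size s+1, success (m−1)/m)."""
        return nbinom(self.s + 1, (self.m - 1) / self.m)


@dataclass(frozen=True)
class AcceptanceInterval:
    """Inclusive integer interval [a, b] holding ≥ 1 − 2α predictive mass."""

    a: int
    b: int
    alpha: float

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.b):
            raise ValueError("need 0 <= a <= b")

    def __contains__(self, x: int) -> bool:
        return self.a <= x <= self.b


def log_predictive_pmf(law: PredictiveLaw, x_next: int) -> float:
    """Log probability of observing ``x_next`` in the held-out replicate."""
    x = np.asarray(x_next)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    s, m = law.s, law.m
    out = (
        gammaln(s + x + 1)
        - gammaln(s + 1)
        - gammaln(x + 1)
        + (s + 1) * (np.log(m - 1) - np.log(m))
        - x * np.log(m)
    )
    return float(out) if np.isscalar(x_next) else out


@lru_cache(maxsize=None)
def _interval(s: int, m: int, alpha: float) -> tuple[int, int]:
    d = PredictiveLaw(s, m).frozen()
    a = int(d.ppf(alpha))  # smallest integer with CDF >= alpha
    while a > 0 and d.cdf(a - 1) >= alpha:
        a -= 1
    while d.cdf(a) < alpha:
        a += 1
    b = max(int(d.ppf(1.0 - alpha)), a)
    while d.sf(b) >= alpha:  # P(X >= b+1) still >= alpha: move up
        b += 1
    while b > a and d.sf(b - 1) < alpha:  # P(X >= b) fell below alpha: move down
        b -= 1
    return a, b


def acceptance_interval(law: PredictiveLaw, alpha: float) -> AcceptanceInterval:
    """Per-tail-α acceptance interval of the predictive law.

    a = smallest integer with cumulative predictive mass ≥ α; b = largest
    integer whose upper-tail mass P(X ≥ b) is ≥ α. The inclusive interval
    then covers more than 1 − 2α of the predictive mass.
    """
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5) — pass a per-tail decimal like 0.01")
    a, b = _interval(law.s, law.m, float(alpha))
    return AcceptanceInterval(a, b, alpha)


def within_consistency(
    reps, alpha: float = 0.01
) -> tuple[bool, list[AcceptanceInterval]]:
    """Leave-one-out replicate-consistency check for one gene.

    For each replicate p the predictive law is built from the other m − 1
    counts (s = Σ_{j≠p} x_j) and x_p is checked against its acceptance
    interval; the gene is consistent only if every replicate passes. The
    verdict does not depend on replicate order.
    """
    counts = np.asarray(getattr(reps, "counts", reps), dtype=np.int64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("consistency check needs at least 2 replicates")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    m = counts.size
    total = int(counts.sum())
    intervals = []
    ok = True
    for p in range(m):
        law = PredictiveLaw(total - int(counts[p]), m)
        iv = acceptance_interval(law, alpha)
        intervals.append(iv)
        ok = ok and int(counts[p]) in iv
    return ok, intervals


def de_bayes(
    x_pooled: int, y_pooled: int, m: int, n: int, alpha: float = 0.01
) -> tuple[bool, AcceptanceInterval]:
    """Two-condition test on pooled counts; requires equal replicate numbers.

    The pooled counts are treated as two replicates of a common law:
    the acceptance interval is built from condition-1 (s = x_pooled, m = 2)
    and the gene is differentially expressed iff y_pooled falls outside it.
    """
    if m != n:
        raise UnequalReplicatesError(
            f"Bayesian two-condition test requires equal replicate numbers (got m={m}, n={n})"
        )
    if m < 1:
        raise ValueError("replicate number must be positive")
    if x_pooled < 0 or y_pooled < 0:
        raise ValueError("pooled counts must be non-negative")
    iv = acceptance_interval(PredictiveLaw(int(x_pooled), 2), alpha)
    return int(y_pooled) not in iv, iv
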