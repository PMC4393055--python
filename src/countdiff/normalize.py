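"""Lane-level normalization of read-count matrices.

Three procedures are provided:

* **TPM** (transcripts parts per million) — each lane scaled so its total
  is 10^6. Note this is the historical per-lane usage for count data, not
  the modern length-adjusted transcript measure.
* **TMM** (trimmed mean of M-values) — per-lane scale factors from a doubly
  trimmed, precision-weighted mean of per-gene log2 ratios against a
  reference lane, removing RNA-composition bias that pure library-size
  scaling cannot.
* **Quantile** — every lane forced to share one reference distribution,
  defined rank-wise as the median across lanes of the rank-sorted values.

All three return a :class:`NormalizationResult` whose matrix has the same
ids and shape as the input and is flagged non-integer; :func:`round_counts`
converts a normalized matrix back to integer counts for the count-based
tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .count_io import CountMatrix
from .errors import DegenerateLaneError, FormatError, InsufficientGenesError

__all__ = [
    "NormalizationResult",
    "normalize_tpm",
    "tmm_scale_factor",
    "normalize_tmm",
    "normalize_quantile",
    "round_counts",
]

MILLION = 1e6


@dataclass
class NormalizationResult:
    normalized: CountMatrix
    scale_factor_of_lane: dict[str, float] | None
    method: str


def _lane_totals(cm: CountMatrix) -> np.ndarray:
    totals = cm.counts.to_numpy().sum(axis=0)
    if (totals <= 0).any():
        lane = cm.lane_ids[int(np.argmax(totals <= 0))]
        raise DegenerateLaneError(f"lane {lane!r} has zero total count")
    return totals


def normalize_tpm(cm: CountMatrix) -> NormalizationResult:
    """Scale every lane to a total of 10^6 (count / lane total × 10^6)."""
    totals = _lane_totals(cm)
    values = cm.counts.to_numpy() / totals * MILLION
    factors = {lane: float(t / MILLION) for lane, t in zip(cm.lane_ids, totals)}
    return NormalizationResult(cm.with_values(values, is_integer=False), factors, "tpm")


def tmm_scale_factor(
    test_lane: np.ndarray,
    ref_lane: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """Relative scale of ``test_lane`` against ``ref_lane``.

    Genes zero in either lane are discarded; the remaining per-gene log2
    ratios M_g = log2(test_g / ref_g) are trimmed by ``trim_m`` at each end
    (and by ``trim_a`` on average log-abundance A_g), then averaged with
    precision weights from the binomial delta-method variance of M_g. The
    result is 2^(weighted mean): 1.0 for identical lanes, and exactly the
    multiplier c when test = c × ref elementwise.
    """
    t = np.asarray(test_lane, dtype=float)
    r = np.asarray(ref_lane, dtype=float)
    if t.shape != r.shape or t.ndim != 1:
        raise FormatError("lanes must be 1-D vectors of equal length")
    n_t, n_r = t.sum(), r.sum()
    if n_t <= 0 or n_r <= 0:
        raise DegenerateLaneError("lane with zero total count")

    keep = (t > 0) & (r > 0)
    t, r = t[keep], r[keep]
    if t.size < 2:
        raise InsufficientGenesError("fewer than 2 genes expressed in both lanes")

    m = np.log2(t / r)
    a = 0.5 * (np.log2(t) + np.log2(r))
    # inverse of the delta-method variance of M_g under binomial sampling
    w = 1.0 / ((n_t - t) / (n_t * t) + (n_r - r) / (n_r * r))

    g = m.size
    keep = _middle_ranks(m, trim_m, g) & _middle_ranks(a, trim_a, g)
    if keep.sum() < 2:
        raise InsufficientGenesError("fewer than 2 genes survive trimming")
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def _middle_ranks(values: np.ndarray, trim: float, g: int) -> np.ndarray:
    """Mask of entries whose (average, tie-shared) rank lies inside the trim band."""
    from scipy.stats import rankdata

    lo = np.floor(g * trim) + 1
    hi = g + 1 - lo
    ranks = rankdata(values, method="average")
    return (ranks >= lo) & (ranks <= hi)


def _reference_lane(cm: CountMatrix) -> int:
    """Index of the lane whose upper quartile is closest to the mean upper quartile."""
    uq = np.percentile(cm.counts.to_numpy(), 75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def normalize_tmm(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationResult:
    """TMM normalization to counts-per-million on effective library sizes.

    The raw relative scale f_j of lane j against the reference lane (from
    :func:`tmm_scale_factor`) contains both the library-size ratio and the
    compositional shift; dividing out the size ratio leaves the
    compositional factor s_j = f_j · N_ref / N_j. Factors are centred to
    geometric mean 1 and each lane is divided by (lane total × factor),
    scaled to a per-million basis. A lane differing from another only by a
    constant multiple normalizes to exactly the same values.
    """
    if len(cm.lane_ids) < 2:
        raise FormatError("TMM requires at least 2 lanes")
    totals = _lane_totals(cm)
    values = cm.counts.to_numpy()
    ref = _reference_lane(cm)
    f = np.array(
        [
            tmm_scale_factor(values[:, j], values[:, ref], trim_m, trim_a)
            for j in range(values.shape[1])
        ]
    )
    comp = f * totals[ref] / totals
    comp /= np.exp(np.mean(np.log(comp)))  # geometric mean 1
    normalized = values / (totals * comp) * MILLION
    factors = {lane: float(s) for lane, s in zip(cm.lane_ids, comp)}
    return NormalizationResult(cm.with_values(normalized, is_integer=False), factors, "tmm")


def normalize_quantile(cm: CountMatrix) -> NormalizationResult:
    """Match every lane to the rank-wise median-across-lanes reference distribution.

    Each lane is sorted; the reference value at rank r is the median over
    lanes of their rank-r values; every entry is replaced by the reference
    value at its within-lane rank, ties receiving the mean of their tied
    ranks' reference values. The map is monotone within each lane and all
    output lanes share one multiset of values.
    """
    if len(cm.lane_ids) < 2:
        raise FormatError("quantile normalization requires at least 2 lanes")
    values = cm.counts.to_numpy()
    reference = np.median(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie groups share the mean reference value of their rank span
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        sums = np.add.reduceat(reference, starts)
        sizes = np.diff(np.r_[starts, sorted_col.size])
        out[order, j] = np.repeat(sums / sizes, sizes)
    return NormalizationResult(cm.with_values(out, is_integer=False), None, "quantile")


def round_counts(norm: NormalizationResult | CountMatrix) -> CountMatrix:
    """Round a normalized matrix to integer counts (half away from zero)."""
    cm = norm.normalized if isinstance(norm, NormalizationResult) else norm
    values = cm.counts.to_numpy()
    rounded = np.floor(np.abs(values) + 0.5) * np.sign(values)
    return cm.with_values(rounded + 0.0, is_integer=True)
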