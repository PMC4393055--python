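"""Differential-expression pipeline: categorize genes, filter, test, summarize.

Genes are stratified by their pooled per-condition counts before testing:

* category 1 — zero in both conditions: nothing can be said, untestable;
* category 2 — zero in exactly one condition and at least ``present_min``
  reads in the other: a presence/absence call, reported DE without a test;
* category 3 — at least ``present_min`` reads in both: tested by the
  likelihood-ratio or the Bayesian predictive method;
* category 0 — anything else (a nonzero count below the presence
  threshold somewhere): indeterminate, excluded from testing.

The default presence threshold is 5 reads. Fold changes are reported as
log2 ratios of per-replicate means with a 0.5 pseudo-count so that
absent-in-one-condition genes still get a finite fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .count_io import RESULT_COLUMNS, CountMatrix, ResultTable
from .errors import MappingError

__all__ = [
    "GeneCategory",
    "categorize",
    "fold_change",
    "run_de",
    "expression_strength_summary",
]

PRESENT_MIN_DEFAULT = 5

CATEGORY_STATUS = {
    0: "indeterminate",
    1: "untestable",
    2: "absent-in-one",
    3: "tested",
}


@dataclass(frozen=True)
class GeneCategory:
    """Testing stratum of one gene, determined by its pooled counts alone."""

    category: int  # 0 indeterminate, 1 both-zero, 2 absent-in-one, 3 present-in-both
    x_pooled: int
    y_pooled: int


def categorize(x_pooled: int, y_pooled: int, present_min: int = PRESENT_MIN_DEFAULT) -> GeneCategory:
    """Assign a gene to a testing stratum from its pooled condition counts."""
    x, y = int(x_pooled), int(y_pooled)
    if x < 0 or y < 0:
        raise ValueError("pooled counts must be non-negative")
    floor = max(present_min, 1)  # "present" always means at least one read
    if x == 0 and y == 0:
        cat = 1
    elif (x == 0) != (y == 0) and max(x, y) >= floor:
        cat = 2
    elif x >= floor and y >= floor:
        cat = 3
    else:
        cat = 0
    return GeneCategory(cat, x, y)


def fold_change(x_pooled: int, m: int, y_pooled: int, n: int) -> float:
    """log2 fold change of per-replicate means with a 0.5 pseudo-count.

    log2((x/m + 0.5) / (y/n + 0.5)); antisymmetric under swapping the
    conditions and finite even when one side is zero.
    """
    return float(np.log2((x_pooled / m + 0.5) / (y_pooled / n + 0.5)))


def run_de(
    cm: CountMatrix,
    method: str = "lrt",
    level_or_alpha: float = 0.01,
    present_min: int = PRESENT_MIN_DEFAULT,
    test_category2: bool = False,
) -> ResultTable:
    """Categorized two-condition DE analysis of a count matrix.

    Category-1 genes are reported untestable, category-2 genes DE by
    absence (pass ``test_category2=True`` to run the test on them instead),
    indeterminate genes are excluded, and category-3 genes are tested with
    the chosen method. ``level_or_alpha`` is the chi-square level for
    ``method="lrt"`` and the per-tail mass for ``method="bayes"``.
    """
    from .bayes import de_bayes
    from .lrt import log_lambda3_between

    if method not in ("lrt", "bayes"):
        raise ValueError(f"unknown method {method!r}; use 'lrt' or 'bayes'")
    labels = cm.condition_labels
    if len(labels) != 2:
        raise MappingError("DE analysis needs exactly two conditions")
    c1, c2 = labels
    m, n = len(cm.lanes_of(c1)), len(cm.lanes_of(c2))
    if method == "bayes" and m != n:
        from .errors import UnequalReplicatesError

        raise UnequalReplicatesError(
            f"Bayesian method requires equal replicate numbers (got m={m}, n={n})"
        )
    xs = np.rint(cm.pooled(c1)).astype(np.int64)
    ys = np.rint(cm.pooled(c2)).astype(np.int64)

    rows = []
    for gene, x, y in zip(cm.gene_ids, xs, ys):
        gc = categorize(x, y, present_min)
        rec = {
            "gene_id": gene,
            "category": gc.category,
            "x_pooled": int(x),
            "y_pooled": int(y),
            "statistic": np.nan,
            "p_value": np.nan,
            "interval_low": np.nan,
            "interval_high": np.nan,
            "log2_fold": fold_change(x, m, y, n),
            "de": False,
            "status": CATEGORY_STATUS[gc.category],
        }
        testable = gc.category == 3 or (gc.category == 2 and test_category2)
        if gc.category == 2 and not test_category2:
            rec["de"] = True  # presence/absence call, no test
        elif testable:
            if method == "lrt":
                r = log_lambda3_between(int(x), m, int(y), n, level=level_or_alpha)
                rec.update(
                    statistic=-2.0 * r.log_statistic, p_value=r.p_value, de=r.reject
                )
            else:
                is_de, iv = de_bayes(int(x), int(y), m, n, alpha=level_or_alpha)
                rec.update(interval_low=iv.a, interval_high=iv.b, de=is_de)
            rec["status"] = "tested"
        rows.append(rec)
    return ResultTable(pd.DataFrame(rows, columns=RESULT_COLUMNS))


def expression_strength_summary(
    cm: CountMatrix, significant_genes, bins: int = 20
) -> dict[str, np.ndarray]:
    """Histograms of expression strength for all genes vs the significant set.

    Strength is log10(1 + mean count per gene over all lanes). Both
    histograms share one set of bin edges spanning the full gene set;
    densities sum to 1 (the significant histogram is all zeros when the
    set is empty).
    """
    significant = set(significant_genes)
    unknown = significant - set(cm.gene_ids)
    if unknown:
        raise MappingError(f"unknown gene id {sorted(unknown)[0]!r}")
    strength = np.log10(1.0 + cm.counts.to_numpy().mean(axis=1))
    edges = np.histogram_bin_edges(strength, bins=bins)
    all_counts, _ = np.histogram(strength, bins=edges)
    mask = np.array([g in significant for g in cm.gene_ids])
    sig_counts, _ = np.histogram(strength[mask], bins=edges)

    def _density(c):
        total = c.sum()
        return c / total if total > 0 else c.astype(float)

    return {
        "bin_edges": edges,
        "all_density": _density(all_counts),
        "significant_density": _density(sig_counts),
    }
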