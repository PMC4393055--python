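import numpy as np
import pandas as pd
import pytest

from countdiff import CountMatrix


def make_matrix(values, conditions=None, gene_ids=None, lane_ids=None) -> CountMatrix:
    values = np.asarray(values, dtype=float)
    g, l = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(g)]
    lane_ids = lane_ids or [f"lane{j + 1}" for j in range(l)]
    if conditions is None:
        half = l // 2
        conditions = {
            lane: ("A" if j < half else "B") for j, lane in enumerate(lane_ids)
        }
    df = pd.DataFrame(values, index=gene_ids, columns=lane_ids)
    is_int = bool(np.all(np.mod(values, 1) == 0))
    return CountMatrix(df, conditions, is_integer=is_int)


def write_tsvs(tmp_path, cm: CountMatrix):
    """Write a CountMatrix and its sample sheet; return the two paths."""
    counts_path = tmp_path / "counts.tsv"
    sheet_path = tmp_path / "samples.tsv"
    cm.write(counts_path)
    with open(sheet_path, "w") as fh:
        fh.write("lane_id\tcondition\n")
        for lane in cm.lane_ids:
            fh.write(f"{lane}\t{cm.conditions[lane]}\n")
    return counts_path, sheet_path


@pytest.fixture
def two_cond_matrix() -> CountMatrix:
    """4 genes × 4 lanes, two conditions with two technical replicates each."""
    return make_matrix(
        [
            [10, 12, 11, 9],
            [0, 0, 0, 0],
            [100, 110, 30, 25],
            [5, 7, 6, 4],
        ]
    )


# Pooled per-condition counts of the five worked-example miRNA genes
# (condition-1 count, condition-2 count, published DE call).
MIRNA_EXAMPLE = [
    ("hsa-let-7g", 15117, 6236, True),
    ("hsa-miR-192", 3711, 2044, True),
    ("hsa-miR-27a", 180, 67, True),
    ("hsa-miR-140-5p", 7, 11, False),
    ("hsa-miR-30b*", 16, 30, False),
]


@pytest.fixture
def mirna_matrix() -> CountMatrix:
    """One lane per condition holding the five worked-example pooled counts."""
    values = [[x, y] for _, x, y, _ in MIRNA_EXAMPLE]
    return make_matrix(
        values,
        gene_ids=[g for g, *_ in MIRNA_EXAMPLE],
        lane_ids=["normal", "tumor"],
        conditions={"normal": "normal", "tumor": "tumor"},
    )
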