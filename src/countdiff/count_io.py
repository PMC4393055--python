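"""Reading, validating and writing gene × lane count matrices and result tables.

File dialect: tab-separated UTF-8, ``#``-prefixed comment lines ignored.
The count matrix has a header row of lane ids and a first column of gene
ids; the sample sheet has columns ``lane_id`` and ``condition`` and must
cover every lane in the matrix header. Gene and lane order from the input
file is preserved everywhere so outputs are diffable.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, MappingError

__all__ = [
    "CountMatrix",
    "ResultTable",
    "RESULT_COLUMNS",
    "read_counts",
    "write_results",
    "read_results",
]


@dataclass
class CountMatrix:
    """Gene × lane read counts with lane→condition labels.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    lane. Entries are non-negative and finite; they are integers for raw
    data and reals after normalization (``is_integer`` records which).
    Lanes map to at most two biological conditions.
    """

    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)
    is_integer: bool = True

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate lane id {dup!r}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric count entries")
        if values.size:
            if not np.all(np.isfinite(values)):
                raise FormatError("non-finite count entries")
            if (values < 0).any():
                raise FormatError("negative count entries")
        missing = [l for l in df.columns if l not in self.conditions]
        if missing:
            raise MappingError(f"lane {missing[0]!r} missing from sample sheet")
        labels = {self.conditions[l] for l in df.columns}
        if len(labels) > 2:
            raise MappingError(
                f"lanes map to {len(labels)} conditions; at most two are supported"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def lane_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def condition_labels(self) -> list[str]:
        """Distinct condition labels in lane order (stable, no sorting)."""
        seen: list[str] = []
        for lane in self.counts.columns:
            c = self.conditions[lane]
            if c not in seen:
                seen.append(c)
        return seen

    def lanes_of(self, condition: str) -> list[str]:
        lanes = [l for l in self.counts.columns if self.conditions[l] == condition]
        if not lanes:
            raise MappingError(f"no lanes for condition {condition!r}")
        return lanes

    def submatrix(self, condition: str) -> np.ndarray:
        """Gene × replicate array for one condition."""
        return self.counts[self.lanes_of(condition)].to_numpy()

    def pooled(self, condition: str) -> np.ndarray:
        """Per-gene sum of counts over the condition's lanes."""
        return self.submatrix(condition).sum(axis=1)

    def with_values(self, values: np.ndarray, *, is_integer: bool) -> "CountMatrix":
        """Same ids/conditions, new entries (used by normalization)."""
        df = pd.DataFrame(values, index=self.counts.index, columns=self.counts.columns)
        return CountMatrix(df, dict(self.conditions), is_integer=is_integer)

    def write(self, path) -> None:
        df = self.counts.copy()
        if self.is_integer:
            df = df.astype(np.int64)
        df.to_csv(path, sep="\t", index_label="gene_id")


# Stable column order of result tables; "statistic" is -2 log Λ for the
# likelihood-ratio method and empty for the Bayesian method, which fills
# the interval columns instead.
RESULT_COLUMNS = [
    "gene_id",
    "category",
    "x_pooled",
    "y_pooled",
    "statistic",
    "p_value",
    "interval_low",
    "interval_high",
    "log2_fold",
    "de",
    "status",
]


@dataclass
class ResultTable:
    """Per-gene DE records, one row per input gene, input order preserved."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RESULT_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"result table missing columns {missing}")
        self.records = (
            self.records[RESULT_COLUMNS]
            .reset_index(drop=True)
            .astype(
                {
                    "category": np.int64,
                    "x_pooled": np.int64,
                    "y_pooled": np.int64,
                    "statistic": float,
                    "p_value": float,
                    "interval_low": float,
                    "interval_high": float,
                    "log2_fold": float,
                    "de": bool,
                    "status": str,
                }
            )
        )
        p = self.records["p_value"].to_numpy(dtype=float)
        ok = np.isnan(p) | ((p >= 0.0) & (p <= 1.0))
        if not ok.all():
            raise FormatError("p-values outside [0, 1]")
        cats = set(self.records["category"].astype(int)) - {0, 1, 2, 3}
        if cats:
            raise FormatError(f"invalid categories {sorted(cats)}")

    def __len__(self) -> int:
        return len(self.records)


def _read_header(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return line.rstrip("\n").split("\t")
    raise FormatError(f"{path}: empty count file")


def read_counts(count_path, samplesheet_path) -> CountMatrix:
    """Read a count matrix TSV and its sample sheet into a CountMatrix.

    Raises FormatError for duplicate ids or negative/non-numeric counts and
    MappingError when a header lane is absent from the sample sheet. Never
    drops rows: the matrix has exactly one row per non-comment file line.
    """
    header = _read_header(count_path)
    lanes = header[1:]
    if len(set(lanes)) != len(lanes):
        raise FormatError(f"{count_path}: duplicate lane id in header")
    try:
        df = pd.read_csv(count_path, sep="\t", comment="#", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas parse failure
        raise FormatError(f"{count_path}: {exc}") from exc
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"{count_path}: non-numeric entry in lane {col!r}")

    sheet = pd.read_csv(samplesheet_path, sep="\t", comment="#", dtype=str)
    for col in ("lane_id", "condition"):
        if col not in sheet.columns:
            raise MappingError(f"{samplesheet_path}: missing column {col!r}")
    conditions = dict(zip(sheet["lane_id"], sheet["condition"]))

    values = df.to_numpy()
    is_int = bool(values.size == 0 or np.all(np.equal(np.mod(values, 1), 0)))
    return CountMatrix(df.astype(float), conditions, is_integer=is_int)


def write_results(table: ResultTable, path) -> None:
    """Write a result table as TSV, floats at full (shortest round-trip) precision."""
    try:
        table.records.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> ResultTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return ResultTable(df)
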