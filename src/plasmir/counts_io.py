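"""Count-matrix and sample-sheet containers, validation, and TSV/CSV I/O.

Counts are integer miRNA-by-sample matrices with unique feature and
sample identifiers.  Sample sheets carry group labels (control / DLBCL /
HL), optional survival columns (``time`` in years, ``event`` in {0,1}),
and an optional ``batch`` column.  Technical sequencing repeats of the
same subject are aggregated by column-wise summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "DLBCL", "HL")
PATIENT_GROUPS = ("DLBCL", "HL")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Non-negative integer read counts, features in rows, samples in columns."""

    counts: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        nf, ns = self.counts.shape
        if nf != len(self.feature_ids) or ns != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.round(self.counts).astype(np.int64)
            if not np.allclose(self.counts, as_int, rtol=0, atol=1e-8):
                i, j = np.argwhere(~np.isclose(self.counts, as_int, rtol=0, atol=1e-8))[0]
                raise ValidationError(
                    f"non-integer count {self.counts[i, j]!r} at "
                    f"feature {self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
                )
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: np.ndarray | Sequence[int]) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.counts[keep, :],
            [self.feature_ids[i] for i in keep],
            list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(
            self.counts[:, idx], list(self.feature_ids), [self.sample_ids[i] for i in idx]
        )


@dataclass
class SampleTable:
    """Per-sample metadata: group label plus optional survival and batch columns."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "sample_id" not in df.columns or "group" not in df.columns:
            raise ValidationError("sample sheet needs 'sample_id' and 'group' columns")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(
                f"unknown group label(s) {bad}; allowed labels: {list(GROUPS)}"
            )
        has_time = "time" in df.columns
        has_event = "event" in df.columns
        if has_time != has_event:
            raise ValidationError("'time' and 'event' columns must be present together")
        if has_time:
            with_time = df["time"].notna()
            if (df.loc[with_time, "time"] <= 0).any():
                raise ValidationError("survival times must be > 0")
            ev = df.loc[df["event"].notna(), "event"]
            if not set(np.unique(ev)) <= {0, 1}:
                raise ValidationError("event must be 0 or 1")
            if (with_time != df["event"].notna()).any():
                raise ValidationError("time and event must be jointly present per sample")
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.frame.set_index("sample_id")["group"]

    @property
    def has_survival(self) -> bool:
        return "time" in self.frame.columns and self.frame["time"].notna().any()

    def ids_in_group(self, group: str) -> list[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        df = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(df)


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_counts(path: str | Path, allow_noninteger: bool = False) -> CountMatrix:
    """Read a delimited count table: first column feature ids, header sample ids.

    TSV by default; comma inferred from a ``.csv`` extension; gzip by
    ``.gz``.  Cells must be non-negative integers.  With
    ``allow_noninteger`` (for upstream batch-corrected matrices),
    numeric cells are rounded to nearest with a warning instead.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"missing value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count table contains non-numeric cells")
    if allow_noninteger and not np.allclose(values, np.round(values), rtol=0, atol=1e-8):
        warnings.warn("non-integer counts rounded to nearest", stacklevel=2)
        values = np.round(values)
    return CountMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().rename_axis("feature_id").to_csv(path, sep=_sep_for(path))


def read_samples(path: str | Path) -> SampleTable:
    """Read a sample sheet (columns: sample_id, group[, time, event, batch])."""
    return SampleTable(pd.read_csv(path, sep=_sep_for(path)))


def write_samples(st: SampleTable, path: str | Path) -> None:
    st.frame.to_csv(path, sep=_sep_for(path), index=False)


def write_table(obj: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table in the package's delimited dialect."""
    obj.to_csv(path, sep=_sep_for(path), index=index)


def aggregate_technical_repeats(
    cm: CountMatrix, mapping: Mapping[str, str]
) -> CountMatrix:
    """Sum columns that map to the same subject id.

    Output column order follows the first occurrence of each subject.
    Total reads are conserved.
    """
    missing = [s for s in cm.sample_ids if s not in mapping]
    if missing:
        raise ValidationError(f"column(s) missing from repeat mapping: {missing}")
    subjects: list[str] = []
    for s in cm.sample_ids:
        subj = str(mapping[s])
        if subj not in subjects:
            subjects.append(subj)
    out = np.zeros((cm.n_features, len(subjects)), dtype=np.int64)
    pos = {subj: k for k, subj in enumerate(subjects)}
    for j, s in enumerate(cm.sample_ids):
        out[:, pos[str(mapping[s])]] += cm.counts[:, j]
    return CountMatrix(out, list(cm.feature_ids), subjects)
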