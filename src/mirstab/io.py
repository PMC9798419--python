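"""Count-matrix and sample-sheet containers with validated TSV/CSV I/O.

A :class:`CountMatrix` is a miRNA × sample table of raw non-negative
integer read counts (tab-separated on disk, feature identifiers in the
first column).  A :class:`SampleTable` carries per-sample annotations:
subject, sampling time in hours (healthy time-course only), condition
(``healthy``/``case``/``control``) and dataset identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("healthy", "case", "control")

#: float format used for every table written by the pipeline (6 sig. digits)
FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CountMatrix:
    """Feature × sample table of raw counts.

    ``counts`` is indexed by feature id with one column per sample id;
    values must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated feature ids: {dups}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = c.columns[
                [not np.issubdtype(d, np.number) for d in c.dtypes]
            ].tolist()
            raise FormatError(f"non-numeric counts in columns: {bad}")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise FormatError(
                f"non-integer count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        self.counts = c.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleTable:
    """Per-sample annotation sheet.

    Columns: ``sample_id``, ``subject_id``, ``timepoint_h`` (may be empty
    for case/control samples), ``condition``, ``dataset_id``.
    """

    frame: pd.DataFrame

    REQUIRED: tuple[str, ...] = field(
        default=("sample_id", "subject_id", "timepoint_h", "condition", "dataset_id"),
        repr=False,
    )

    def __post_init__(self) -> None:
        f = self.frame
        if f.empty:
            raise FormatError("sample table is empty")
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        if f["sample_id"].duplicated().any():
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        bad = sorted(set(f["condition"]) - set(CONDITIONS))
        if bad:
            raise FormatError(
                f"unknown condition values {bad}; allowed: {list(CONDITIONS)}"
            )
        f = f.copy()
        f["timepoint_h"] = pd.to_numeric(f["timepoint_h"], errors="coerce")
        healthy = f["condition"] == "healthy"
        if f.loc[healthy, "timepoint_h"].isna().any():
            ids = f.loc[healthy & f["timepoint_h"].isna(), "sample_id"].tolist()
            raise FormatError(f"healthy samples missing timepoint_h: {ids}")
        if (f.loc[healthy, "timepoint_h"] < 0).any():
            raise FormatError("timepoint_h must be non-negative")
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def timepoints_h(self) -> list[float]:
        tp = self.frame["timepoint_h"].dropna().unique()
        return sorted(float(t) for t in tp)

    def samples_at(self, timepoint_h: float) -> list[str]:
        sel = self.frame["timepoint_h"] == timepoint_h
        return self.frame.loc[sel, "sample_id"].tolist()

    def by_condition(self, condition: str) -> list[str]:
        sel = self.frame["condition"] == condition
        return self.frame.loc[sel, "sample_id"].tolist()


def check_paired(cm: CountMatrix, st: SampleTable) -> None:
    """Verify that matrix columns and sheet rows describe the same samples."""
    mat, sheet = set(cm.sample_ids), set(st.sample_ids)
    if mat != sheet:
        only_m = sorted(mat - sheet)[:5]
        only_s = sorted(sheet - mat)[:5]
        raise FormatError(
            f"sample mismatch between matrix and sheet; matrix-only={only_m}, sheet-only={only_s}"
        )


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a tab-separated count table (feature ids in the first column)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must name at least one sample column")
    names = header[1:]
    dups = sorted({n for n in names if names.count(n) > 1})
    if dups:
        raise FormatError(f"{path}: duplicated sample columns: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path} contains no samples")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a CSV sample sheet."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str, "dataset_id": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.frame.to_csv(path, index=False)
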