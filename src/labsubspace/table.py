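"""Tabular container for per-subject laboratory panels, plus the study protocol's
preprocessing steps: cohort inclusion filtering, 0-10 min-max normalization and
arithmetic parameter grids.

The central object is :class:`LabTable`, an ``n_subjects x n_attributes`` numeric
matrix with attribute names, subject identifiers and optional outcome metadata
(6-month mortality, survival days, baseline-panel availability).  Rows keep file
order throughout; every clustering algorithm in this package addresses subjects
by 0-based row position in the filtered, normalized table.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabTable",
    "InclusionCriteria",
    "ParamGrid",
    "load_table",
    "write_table",
    "apply_inclusion_filter",
    "normalize",
    "make_param_grid",
]


@dataclass
class LabTable:
    """Subjects x attributes matrix of laboratory values with optional metadata.

    Parameters
    ----------
    values
        ``(n, d)`` float array.  Lab units before normalization, dimensionless
        in ``[lo, hi]`` after :func:`normalize`.
    attribute_names
        Length-``d`` list of column names.
    subject_ids
        Length-``n`` list of unique opaque identifiers.
    mortality
        Optional length-``n`` 0/1 array: dead (1) / alive (0) at 6 months.
    survival_days
        Optional length-``n`` non-negative integer array.
    baseline_available
        Optional length-``n`` boolean array; False marks subjects whose
        baseline panel is incomplete.
    """

    values: np.ndarray
    attribute_names: list[str]
    subject_ids: list[str]
    mortality: np.ndarray | None = None
    survival_days: np.ndarray | None = None
    baseline_available: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.attribute_names) != d:
            raise ValueError(
                f"{len(self.attribute_names)} attribute names for {d} columns"
            )
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        dupes = pd.Index(self.subject_ids)[pd.Index(self.subject_ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate subject id(s): {sorted(set(map(str, dupes)))}")
        for name in ("mortality", "survival_days", "baseline_available"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (n,):
                    raise ValueError(f"{name} must have length {n}")
                setattr(self, name, arr)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "LabTable":
        """Row-subset (boolean mask or index array), preserving order."""
        rows = np.asarray(rows)
        take = lambda a: None if a is None else a[rows]
        ids = list(np.asarray(self.subject_ids, dtype=object)[rows])
        return LabTable(
            values=self.values[rows],
            attribute_names=list(self.attribute_names),
            subject_ids=ids,
            mortality=take(self.mortality),
            survival_days=take(self.survival_days),
            baseline_available=take(self.baseline_available),
        )

    def to_frame(self, schema: dict | None = None) -> pd.DataFrame:
        """Assemble a DataFrame with metadata columns named per ``schema``
        (keys ``id_col``, ``label_col``, ``survival_col``, ``baseline_col``)."""
        schema = {**_DEFAULT_SCHEMA, **(schema or {})}
        df = pd.DataFrame({schema["id_col"]: self.subject_ids})
        if self.survival_days is not None:
            df[schema["survival_col"]] = self.survival_days
        if self.baseline_available is not None:
            df[schema["baseline_col"]] = self.baseline_available.astype(int)
        if self.mortality is not None:
            df[schema["label_col"]] = self.mortality
        for j, name in enumerate(self.attribute_names):
            df[name] = self.values[:, j]
        return df


_DEFAULT_SCHEMA = {
    "id_col": "subject_id",
    "label_col": "mortality",
    "survival_col": "survival_days",
    "baseline_col": "baseline_available",
}


def load_table(path: str | Path, schema: dict | None = None) -> LabTable:
    """Read a header-ed CSV into a :class:`LabTable`.

    ``schema`` maps column roles (``id_col``, ``label_col``, ``survival_col``,
    ``baseline_col``) to column names; every other column is treated as a
    numeric clustering attribute.  Rows with unparseable numeric cells are not
    dropped: the offending cells become NaN and the row is flagged
    ``baseline_available=False``, so the standard inclusion filter removes it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = {**_DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    meta_cols = [
        c
        for c in (
            schema["id_col"],
            schema["label_col"],
            schema["survival_col"],
            schema["baseline_col"],
        )
        if c in df.columns
    ]
    attr_cols = [c for c in df.columns if c not in meta_cols]
    if not attr_cols:
        raise ValueError("no attribute columns found")
    values = df[attr_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)

    incomplete = np.isnan(values).any(axis=1)
    if schema["baseline_col"] in df.columns:
        baseline = df[schema["baseline_col"]].astype(bool).to_numpy() & ~incomplete
    elif incomplete.any():
        baseline = ~incomplete
    else:
        baseline = None

    if schema["id_col"] in df.columns:
        ids = [str(v) for v in df[schema["id_col"]]]
    else:
        ids = [str(i) for i in range(len(df))]

    mortality = None
    if schema["label_col"] in df.columns:
        mortality = df[schema["label_col"]].to_numpy()
    survival = None
    if schema["survival_col"] in df.columns:
        survival = df[schema["survival_col"]].to_numpy()

    return LabTable(
        values=values,
        attribute_names=attr_cols,
        subject_ids=ids,
        mortality=mortality,
        survival_days=survival,
        baseline_available=baseline,
    )


def write_table(table: LabTable, path: str | Path, schema: dict | None = None) -> None:
    """Write a table back to CSV (round-trips with :func:`load_table`)."""
    table.to_frame(schema).to_csv(path, index=False)


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort inclusion rules: survive at least ``min_survival_days`` days,
    optionally require a complete baseline lab panel, optionally honour the
    parent study's exclusions (encoded here as ``baseline_available`` /
    ``survival_days`` metadata)."""

    min_survival_days: int = 3
    require_baseline_labs: bool = True
    exclude_parent_excluded: bool = False

    def __post_init__(self) -> None:
        if self.min_survival_days < 0:
            raise ValueError("min_survival_days must be >= 0")


def apply_inclusion_filter(
    table: LabTable, criteria: InclusionCriteria
) -> tuple[LabTable, dict[str, int]]:
    """Restrict a table to subjects meeting ALL enabled criteria.

    Returns the filtered table (original row order preserved) and a per-criterion
    count of excluded subjects.  The survival bound is inclusive: a subject with
    ``survival_days == min_survival_days`` stays in.
    """
    n = table.n_subjects
    keep = np.ones(n, dtype=bool)
    excluded: dict[str, int] = {}

    if criteria.min_survival_days > 0:
        if table.survival_days is None:
            raise ValueError("survival filter enabled but survival_days missing")
        ok = np.asarray(table.survival_days) >= criteria.min_survival_days
        excluded["min_survival_days"] = int((~ok).sum())
        keep &= ok
    if criteria.require_baseline_labs:
        if table.baseline_available is None:
            # no availability column and no missing cells: everyone qualifies
            excluded["require_baseline_labs"] = 0
        else:
            ok = np.asarray(table.baseline_available, dtype=bool)
            excluded["require_baseline_labs"] = int((~ok).sum())
            keep &= ok
    return table.subset(keep), excluded


def normalize(table: LabTable, lo: float = 0.0, hi: float = 10.0) -> LabTable:
    """Independently min-max rescale each attribute column onto ``[lo, hi]``.

    Each column's observed minimum maps to ``lo`` and maximum to ``hi``; a
    constant column maps to ``lo`` everywhere (any constant is equally
    arbitrary; ``lo`` is reproducible).
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if table.n_subjects < 1:
        raise ValueError("cannot normalize an empty table")
    X = table.values
    mins = X.min(axis=0)
    span = X.max(axis=0) - mins
    out = np.full_like(X, lo)
    nz = span > 0
    out[:, nz] = lo + (X[:, nz] - mins[nz]) / span[nz] * (hi - lo)
    new = dataclasses.replace(table)
    new.values = out
    return new


@dataclass(frozen=True)
class ParamGrid:
    """Arithmetic grid ``start, start+step, ... <= max`` (inclusive of ``max``
    when it is reached within 1e-9)."""

    start: float
    step: float
    max: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.start > self.max:
            raise ValueError("start must not exceed max")


def make_param_grid(grid: ParamGrid, tol: float = 1e-9) -> list[float]:
    """Expand a :class:`ParamGrid` into its ordered list of values."""
    count = int(math.floor((grid.max - grid.start) / grid.step + tol)) + 1
    return [grid.start + i * grid.step for i in range(count)]
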