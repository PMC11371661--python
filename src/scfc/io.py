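"""Boundary I/O and validated in-memory containers for connectome data.

All file formats are plain tab-separated text:

* connectivity matrix — ``n x n`` numeric TSV, optional ``#``-prefixed header
  row of region labels and an optional first column of labels;
* time series — ``n_regions x T`` TSV with the same label conventions;
* module partition — two columns, ``region<TAB>module``;
* cohort table — TSV with a header row; missing scores are written ``NA``.

Connectivity matrices must be complete (no ``NA``), square, symmetric, with a
zero diagonal; cohort score columns may carry missing values, which downstream
statistics drop pairwise.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "TimeSeriesMatrix",
    "ModulePartition",
    "CohortTable",
    "ValidationError",
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_partition",
    "write_partition",
    "default_partition",
    "read_cohort",
    "write_cohort",
]

SYMMETRY_TOL = 1e-9

#: cohort columns that must always be present
COHORT_REQUIRED = ("id", "group", "age", "sex", "education", "head_motion")
#: cognitive score columns recognised by the inference layer
SCORE_COLUMNS = ("MoCA", "AVLT", "SCWT", "SDMT", "TMT")
#: optional binary history/burden markers
MARKER_COLUMNS = (
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "smoking",
    "lacunes",
    "wmh",
    "pvs",
    "cmb",
)


class ValidationError(ValueError):
    """An input violates a structural invariant of its container type."""


@dataclasses.dataclass(frozen=True)
class ConnectivityMatrix:
    """A square, symmetric, nonnegative-weight region-by-region network.

    Parameters
    ----------
    region_labels
        Ordered region identifiers, one per row/column.
    weights
        ``(n, n)`` float array. Functional weights must lie in ``[-1, 1]``
        (``[0, 1]`` under the default absolute-correlation convention);
        structural weights must be >= 0.
    kind
        Either ``"functional"`` or ``"structural"``.
    """

    region_labels: tuple[str, ...]
    weights: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "region_labels", tuple(str(x) for x in self.region_labels))
        if self.kind not in ("functional", "structural"):
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {w.shape}")
        n = w.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 regions, got {n}")
        if len(self.region_labels) != n:
            raise ValidationError(
                f"{len(self.region_labels)} labels for {n}x{n} matrix"
            )
        if len(set(self.region_labels)) != n:
            raise ValidationError("duplicate region labels")
        if not np.all(np.isfinite(w)):
            raise ValidationError("matrix contains non-finite values")
        if np.abs(w - w.T).max() > SYMMETRY_TOL:
            raise ValidationError(
                f"matrix asymmetric beyond tolerance {SYMMETRY_TOL:g}"
            )
        if np.any(np.diag(w) != 0.0):
            raise ValidationError("diagonal must be exactly zero")
        if self.kind == "structural" and w.min() < 0:
            raise ValidationError("structural weights must be nonnegative")
        if self.kind == "functional" and (w.max() > 1.0 + 1e-12 or w.min() < -1.0 - 1e-12):
            raise ValidationError("functional weights must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def reorder(self, labels: Sequence[str]) -> "ConnectivityMatrix":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        idx = _permutation(self.region_labels, labels)
        return ConnectivityMatrix(
            tuple(labels), self.weights[np.ix_(idx, idx)], self.kind
        )


@dataclasses.dataclass(frozen=True)
class TimeSeriesMatrix:
    """Region-averaged BOLD-like time series, one row per region."""

    region_labels: tuple[str, ...]
    samples: np.ndarray
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "region_labels", tuple(str(v) for v in self.region_labels))
        if x.ndim != 2:
            raise ValidationError("time series must be a 2-D array")
        if x.shape[1] < 3:
            raise ValidationError(f"need T >= 3 samples, got {x.shape[1]}")
        if len(self.region_labels) != x.shape[0]:
            raise ValidationError("label count does not match row count")
        if not np.all(np.isfinite(x)):
            raise ValidationError("time series contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def constant_regions(self) -> list[str]:
        """Labels of regions whose series have (numerically) zero variance."""
        sd = self.samples.std(axis=1)
        return [lab for lab, s in zip(self.region_labels, sd) if s == 0.0]


@dataclasses.dataclass(frozen=True)
class ModulePartition:
    """Assignment of every region to exactly one named module."""

    assignment: Mapping[str, str]
    module_names: tuple[str, ...]

    def __post_init__(self) -> None:
        assign = dict(self.assignment)
        object.__setattr__(self, "assignment", assign)
        names = tuple(self.module_names)
        object.__setattr__(self, "module_names", names)
        seen = set(assign.values())
        missing = [m for m in names if m not in seen]
        if missing:
            raise ValidationError(f"empty modules: {missing}")
        unknown = seen - set(names)
        if unknown:
            raise ValidationError(f"modules not in declared order: {sorted(unknown)}")

    @classmethod
    def from_assignment(cls, assignment: Mapping[str, str]) -> "ModulePartition":
        names: list[str] = []
        for m in assignment.values():
            if m not in names:
                names.append(m)
        return cls(assignment, tuple(names))

    @property
    def region_labels(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def module_of(self, region: str) -> str:
        return self.assignment[region]

    def regions_of(self, module: str) -> tuple[str, ...]:
        return tuple(r for r, m in self.assignment.items() if m == module)

    def sizes(self) -> dict[str, int]:
        out = {m: 0 for m in self.module_names}
        for m in self.assignment.values():
            out[m] += 1
        return out

    def indices(self, labels: Sequence[str]) -> dict[str, np.ndarray]:
        """Per-module integer indices into a matrix ordered as ``labels``."""
        self.validate_against(labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        return {
            m: np.array(sorted(pos[r] for r in self.regions_of(m)), dtype=int)
            for m in self.module_names
        }

    def validate_against(self, labels: Sequence[str]) -> None:
        labels = list(labels)
        missing = [lab for lab in labels if lab not in self.assignment]
        if missing:
            raise ValidationError(f"regions without module assignment: {missing}")
        extra = [r for r in self.assignment if r not in set(labels)]
        if extra:
            raise ValidationError(f"partition names unknown regions: {extra}")


class CohortTable:
    """Per-subject group membership, covariates and cognitive scores.

    Thin wrapper over a :class:`pandas.DataFrame` that enforces unique ids, a
    declared group-label set, finite covariates, and ``{0, 1}`` sex coding.
    Cognitive scores may be missing (NaN) and are excluded pairwise downstream.
    """

    def __init__(self, frame: pd.DataFrame, group_order: Sequence[str] | None = None):
        df = frame.copy().reset_index(drop=True)
        for col in COHORT_REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"cohort table missing column {col!r}")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate subject ids: {dupes}")
        df["group"] = df["group"].astype(str)
        if group_order is None:
            group_order = list(dict.fromkeys(df["group"]))
        unknown = set(df["group"]) - set(group_order)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        for col in ("age", "sex", "education", "head_motion"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), "id"].tolist()
                raise ValidationError(f"non-numeric/missing {col} for subjects {bad}")
            df[col] = vals.astype(float)
        if not df["sex"].isin([0.0, 1.0]).all():
            raise ValidationError("sex must be coded 0/1")
        for col in df.columns:
            if col in ("id", "group"):
                continue
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        self.frame = df
        self.group_order = tuple(group_order)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.group_order == other.group_order and self.frame.equals(other.frame)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.frame["id"])

    @property
    def score_columns(self) -> tuple[str, ...]:
        return tuple(c for c in SCORE_COLUMNS if c in self.frame.columns)

    @property
    def marker_columns(self) -> tuple[str, ...]:
        return tuple(c for c in MARKER_COLUMNS if c in self.frame.columns)

    def group_of(self, subject_id: str) -> str:
        row = self.frame.loc[self.frame["id"] == subject_id, "group"]
        if row.empty:
            raise KeyError(subject_id)
        return row.iloc[0]

    def subset(self, group: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == group]


# ---------------------------------------------------------------------------
# readers / writers


def _permutation(current: Sequence[str], target: Sequence[str]) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(current)}
    missing = [lab for lab in target if lab not in pos]
    if missing:
        raise ValidationError(f"labels not present in matrix: {missing}")
    if len(target) != len(current):
        raise ValidationError("label reordering must be a permutation")
    return np.array([pos[lab] for lab in target], dtype=int)


def _parse_table(path: Path) -> tuple[list[str] | None, list[str] | None, np.ndarray]:
    """Parse a numeric TSV with optional '#' label header and label column."""
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                fields = line.lstrip("#").strip().split("\t")
                if fields and any(f for f in fields):
                    header = fields
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    row_labels: list[str] | None = None
    first_cells = [r[0] for r in rows]
    if not all(_is_number(c) for c in first_cells):
        row_labels = first_cells
        rows = [r[1:] for r in rows]
    ncol = len(rows[0])
    data = np.empty((len(rows), ncol), dtype=float)
    for i, r in enumerate(rows):
        if len(r) != ncol:
            raise ValidationError(
                f"{path}: row {i + 1} has {len(r)} columns, expected {ncol}"
            )
        for j, cell in enumerate(r):
            if cell == "NA":
                raise ValidationError(f"{path}: NA at row {i + 1}, col {j + 1}")
            if not _is_number(cell):
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, col {j + 1}"
                )
            data[i, j] = float(cell)
    return header, row_labels, data


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def read_matrix(
    path: str | Path,
    kind: str,
    partition: ModulePartition | None = None,
) -> ConnectivityMatrix:
    """Read a connectivity matrix from a TSV file.

    When ``partition`` is given, regions are permuted into the partition's
    order so all downstream indexing is label-aligned.
    """
    path = Path(path)
    header, row_labels, data = _parse_table(path)
    if data.shape[0] != data.shape[1]:
        raise ValidationError(
            f"{path}: matrix is {data.shape[0]}x{data.shape[1]}, must be square"
        )
    labels = row_labels or header
    if labels is None:
        labels = [f"R{i + 1:02d}" for i in range(data.shape[0])]
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: matrix contains NaN/Inf")
    m = ConnectivityMatrix(tuple(labels), data, kind)
    if partition is not None:
        m = m.reorder(partition.region_labels)
    return m


def write_matrix(m: ConnectivityMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#\t" + "\t".join(m.region_labels) + "\n")
        for lab, row in zip(m.region_labels, m.weights):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(path: str | Path, sampling_interval: float = 1.0) -> TimeSeriesMatrix:
    path = Path(path)
    _, row_labels, data = _parse_table(path)
    labels = row_labels or [f"R{i + 1:02d}" for i in range(data.shape[0])]
    return TimeSeriesMatrix(tuple(labels), data, sampling_interval)


def write_timeseries(ts: TimeSeriesMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(ts.region_labels, ts.samples):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_partition(
    path: str | Path, regions: Sequence[str] | None = None
) -> ModulePartition:
    """Read a two-column region->module table and validate completeness."""
    path = Path(path)
    assignment: dict[str, str] = {}
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 2"
                )
            region, module = fields[0].strip(), fields[1].strip()
            if region in assignment:
                if assignment[region] != module:
                    raise ValidationError(
                        f"{path}: region {region!r} assigned to both "
                        f"{assignment[region]!r} and {module!r}"
                    )
                raise ValidationError(f"{path}: duplicate row for region {region!r}")
            assignment[region] = module
            if module not in names:
                names.append(module)
    part = ModulePartition(assignment, tuple(names))
    if regions is not None:
        part.validate_against(regions)
    return part


def write_partition(p: ModulePartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for region, module in p.assignment.items():
            fh.write(f"{region}\t{module}\n")


def default_partition() -> ModulePartition:
    """The shipped five-module partition of a 90-region parcellation.

    A synthetic stand-in for the common five-way functional division
    (auditory/motor 20, vision 14, attention 18, default-mode 18,
    limbic/subcortical 20 regions); replace with an atlas-specific table for
    real data.
    """
    res = importlib.resources.files("scfc.data").joinpath("default_partition_90.tsv")
    with importlib.resources.as_file(res) as path:
        return read_partition(path)


def read_cohort(
    path: str | Path, group_order: Sequence[str] | None = None
) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"], comment=None)
    return CohortTable(df, group_order)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    df = cohort.frame.copy()
    float_cols = [c for c in df.columns if df[c].dtype.kind == "f"]
    for c in float_cols:
        df[c] = df[c].map(lambda v: "NA" if pd.isna(v) else f"{v:.17g}")
    df.to_csv(path, sep="\t", index=False)
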