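"""Delimited-text I/O for clinical tables with explicit missing markers.

Values are kept as an n x m float matrix with a parallel boolean mask;
masked cells hold NaN so nothing downstream can silently read an absent
measurement as a number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .schema import DatasetSchema, normalize_name

DEFAULT_MISSING_MARKERS = frozenset({"?", "", "NA"})


@dataclass
class TabularDataset:
    """A numeric table, its missingness mask, and binary labels.

    ``values[i, j]`` is NaN wherever ``missing[i, j]`` is True; use
    :meth:`observed` for a masked-array view that errors on accidental use.
    """

    values: np.ndarray
    missing: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    schema: DatasetSchema | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape mismatch")
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels length mismatch")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(np.int64)
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")
        # enforce the sentinel contract
        self.values = self.values.copy()
        self.values[self.missing] = np.nan

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def observed(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.missing)

    def copy(self) -> "TabularDataset":
        return TabularDataset(self.values.copy(), self.missing.copy(),
                              self.labels.copy(), list(self.feature_names),
                              self.schema)

    def is_complete(self) -> bool:
        return not self.missing.any()


def _parse_label(token: str, path, row: int):
    try:
        lab = int(float(token))
    except ValueError:
        raise ValueError(f"{path}: row {row}: label {token!r} is not numeric") from None
    if lab not in (0, 1):
        raise ValueError(f"{path}: row {row}: label {token!r} not in {{0,1}}")
    return lab


def load_table(path, missing_markers=DEFAULT_MISSING_MARKERS,
               label_column: str = "Class",
               schema: DatasetSchema | None = None) -> TabularDataset:
    """Read a CSV with a header row into a :class:`TabularDataset`.

    Cells equal to any token in ``missing_markers`` are masked. All other
    cells must parse as numbers; a cell that does neither raises a parse
    error naming its row and column. The label column (matched
    case-insensitively with whitespace normalization) must code 0/1.
    """
    markers = set(missing_markers)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        rows = list(reader)

    keyed = [normalize_name(h) for h in header]
    want = normalize_name(label_column)
    if want not in keyed:
        raise ValueError(f"{path}: label column {label_column!r} not found")
    label_idx = keyed.index(want)
    feat_names = [h for i, h in enumerate(header) if i != label_idx]

    n, m = len(rows), len(header) - 1
    values = np.full((n, m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    labels = np.empty(n, dtype=np.int64)
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise ValueError(f"{path}: row {i + 1}: expected {len(header)} fields, got {len(row)}")
        tok = row[label_idx].strip()
        if tok in markers:
            raise ValueError(f"{path}: row {i + 1}: missing label")
        labels[i] = _parse_label(tok, path, i + 1)
        j = 0
        for c, cell in enumerate(row):
            if c == label_idx:
                continue
            cell = cell.strip()
            if cell in markers:
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: row {i + 1}, column {header[c]!r}: "
                        f"unparseable cell {cell!r}") from None
            j += 1
    return TabularDataset(values, mask, labels, feat_names, schema)


def _fmt(x: float) -> str:
    # repr() is the shortest exact decimal for a float, so save->load
    # round-trips bit-exactly; integers print without a trailing ".0"
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def save_table(ds: TabularDataset, path, missing_marker: str = "?",
               label_column: str | None = None) -> None:
    """Write the dataset as CSV; masked cells become ``missing_marker``."""
    label = label_column or (ds.schema.label_name if ds.schema else "Class")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(ds.feature_names) + [label])
        for i in range(ds.n_samples):
            row = [missing_marker if ds.missing[i, j] else _fmt(ds.values[i, j])
                   for j in range(ds.n_features)]
            row.append(str(int(ds.labels[i])))
            writer.writerow(row)


@dataclass
class MissingnessSummary:
    per_feature: np.ndarray        # fraction masked per column
    overall: float                 # fraction masked over all cells
    n_complete_rows: int           # rows with zero masked cells


def missingness_summary(ds: TabularDataset) -> MissingnessSummary:
    per_feature = ds.missing.mean(axis=0)
    overall = float(ds.missing.mean()) if ds.missing.size else 0.0
    complete = int((~ds.missing.any(axis=1)).sum())
    return MissingnessSummary(per_feature, overall, complete)


@dataclass(frozen=True)
class SchemaViolation:
    row: int
    column: int
    feature: str
    value: float
    reason: str


def validate_against_schema(ds: TabularDataset, schema: DatasetSchema) -> list[SchemaViolation]:
    """Check unmasked cells against the schema's ranges and integer scales.

    Returns one record per offending cell; an empty list means the table is
    consistent with the schema. Column count must match the schema.
    """
    if ds.n_features != len(schema):
        raise ValueError(
            f"dataset has {ds.n_features} feature columns, schema has {len(schema)}")
    violations: list[SchemaViolation] = []
    for j, spec in enumerate(schema.features):
        col = ds.values[:, j]
        obs = ~ds.missing[:, j]
        for i in np.nonzero(obs)[0]:
            v = col[i]
            if not (spec.low <= v <= spec.high):
                violations.append(SchemaViolation(
                    int(i), j, spec.name, float(v),
                    f"value outside [{spec.low}, {spec.high}]"))
            elif spec.qualitative and v != int(v):
                violations.append(SchemaViolation(
                    int(i), j, spec.name, float(v),
                    f"non-integer value for {spec.kind} feature"))
    return violations
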