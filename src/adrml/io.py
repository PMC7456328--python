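"""Core containers and text-format readers/writers.

All tabular data are exchanged as labelled TSV/CSV matrices: first row is
the column labels, first column the row labels, "NA" (or an empty field)
marks a missing value.  Gene sets use the standard MSigDB GMT dialect.
Alignment between tables is always by label, never by position.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Feature kinds with continuous values (similarity via Pearson correlation).
CONTINUOUS_KINDS = frozenset({"EXPR", "CNV"})
#: Feature kinds with binary values (similarity via Jaccard index).
BINARY_KINDS = frozenset({"MUT", "CHEM", "TRGT", "KEGG"})
FEATURE_KINDS = CONTINUOUS_KINDS | BINARY_KINDS

MISSING_TOKENS = ("NA", "")


class ParseError(ValueError):
    """Raised when a text input file violates the expected layout."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ParseError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass
class ResponseMatrix:
    """Cell-line x drug log IC50 grid with an observed-entry mask.

    ``values[i, j]`` is the log IC50 of drug ``drug_ids[j]`` on cell line
    ``cell_ids[i]``; ``observed_mask[i, j]`` is True where the entry is
    known.  Unobserved entries hold NaN.
    """

    cell_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray
    observed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        n, m = len(self.cell_ids), len(self.drug_ids)
        if self.values.shape != (n, m) or self.observed_mask.shape != (n, m):
            raise ValueError(
                f"shape mismatch: {n} cells x {m} drugs vs values "
                f"{self.values.shape}, mask {self.observed_mask.shape}"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.drug_ids, "drug")
        if not np.all(np.isfinite(self.values[self.observed_mask])):
            raise ValueError("observed response entries must be finite")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def copy(self) -> "ResponseMatrix":
        return ResponseMatrix(
            list(self.cell_ids),
            list(self.drug_ids),
            self.values.copy(),
            self.observed_mask.copy(),
        )


@dataclass
class FeatureTable:
    """Entity x feature table with a kind tag and missing mask.

    ``kind`` is one of EXPR/CNV (continuous) or MUT/CHEM/TRGT/KEGG
    (binary).  Binary kinds must hold only 0/1 in non-missing cells, and
    expression tables may not contain missing values at all.
    """

    entity_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    kind: str
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = len(self.entity_ids), len(self.feature_ids)
        if self.values.shape != (n, p) or self.missing_mask.shape != (n, p):
            raise ValueError(
                f"shape mismatch: {n} entities x {p} features vs values "
                f"{self.values.shape}, mask {self.missing_mask.shape}"
            )
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        _check_unique(self.entity_ids, "entity")
        _check_unique(self.feature_ids, "feature")
        if self.kind == "EXPR" and self.missing_mask.any():
            raise ValueError("expression tables may not contain missing values")
        if self.kind in BINARY_KINDS:
            present = self.values[~self.missing_mask]
            if not np.all(np.isin(present, (0.0, 1.0))):
                bad = np.argwhere(~np.isin(self.values, (0.0, 1.0)) & ~self.missing_mask)
                i, j = bad[0]
                raise ValueError(
                    f"binary table of kind {self.kind} holds non-binary value "
                    f"{self.values[i, j]!r} at ({self.entity_ids[i]!r}, "
                    f"{self.feature_ids[j]!r})"
                )

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.entity_ids),
            list(self.feature_ids),
            self.values.copy(),
            self.kind,
            self.missing_mask.copy(),
        )

    def row(self, entity: str) -> np.ndarray:
        try:
            idx = self.entity_ids.index(entity)
        except ValueError:
            raise KeyError(f"unknown entity label {entity!r}") from None
        return self.values[idx]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over a set of labelled entities.

    ``normalized`` is False for a raw similarity (Pearson or Jaccard) and
    True once the symmetric normalized Laplacian has been applied.
    """

    entity_ids: list[str]
    values: np.ndarray
    kind: str | None = None
    normalized: bool = False

    _SYM_TOL = 1e-10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity must be {n}x{n}, got {self.values.shape}")
        _check_unique(self.entity_ids, "entity")
        if n and np.max(np.abs(self.values - self.values.T)) > self._SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def reindex(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Restrict/reorder to ``ids`` (each must be present)."""
        pos = {lab: i for i, lab in enumerate(self.entity_ids)}
        try:
            idx = np.array([pos[lab] for lab in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} absent from similarity matrix") from None
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind, self.normalized)


@dataclass
class GeneSetCollection:
    """Named gene sets (pathway label -> ordered gene list, no duplicates)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class TissueAnnotation:
    """Mapping from cell-line label to tissue/cancer-type label."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, tissue in self.mapping.items():
            if not tissue:
                raise ValueError(f"cell {cell!r} has an empty tissue label")

    def tissue_of(self, cell: str) -> str:
        try:
            return self.mapping[cell]
        except KeyError:
            raise KeyError(f"cell {cell!r} has no tissue annotation") from None

    def by_tissue(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for cell, tissue in self.mapping.items():
            out.setdefault(tissue, []).append(cell)
        return out


# ---------------------------------------------------------------------------
# Readers / writers


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_cell(token: str, row_label: str, col_label: str, binary: bool):
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan, True
    try:
        value = float(token)
    except ValueError:
        raise ParseError(
            f"non-numeric value {token!r} at ({row_label!r}, {col_label!r})"
        ) from None
    if binary and value not in (0.0, 1.0):
        raise ParseError(
            f"binary matrix holds value {token!r} outside {{0,1}} at "
            f"({row_label!r}, {col_label!r})"
        )
    return value, False


def read_labelled_matrix(
    path: str | Path, value_domain: str = "real"
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Parse a labelled TSV/CSV matrix.

    Returns ``(row_ids, col_ids, values, missing_mask)``.  The delimiter is
    taken from the extension (``.csv`` -> comma, otherwise tab).  With
    ``value_domain='binary'`` any non-missing value outside {0, 1} is a
    parse error.
    """
    if value_domain not in ("real", "binary"):
        raise ValueError(f"value_domain must be 'real' or 'binary', got {value_domain!r}")
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    rows = [r for r in rows if r]  # drop blank lines
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    col_ids = [c.strip() for c in header[1:]]
    _check_unique(col_ids, "column")
    n_cols = len(col_ids)
    row_ids: list[str] = []
    values = np.empty((len(rows) - 1, n_cols), dtype=float)
    missing = np.zeros_like(values, dtype=bool)
    for r, fields in enumerate(rows[1:], start=2):
        if len(fields) != n_cols + 1:
            raise ParseError(
                f"{path}: row {r} has {len(fields)} fields, expected {n_cols + 1}"
            )
        label = fields[0].strip()
        row_ids.append(label)
        for c, token in enumerate(fields[1:]):
            values[r - 2, c], missing[r - 2, c] = _parse_cell(
                token, label, col_ids[c], value_domain == "binary"
            )
    _check_unique(row_ids, "row")
    return row_ids, col_ids, values, missing


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    """Read a cell x drug log IC50 matrix ("NA"/empty cells are unobserved)."""
    cells, drugs, values, missing = read_labelled_matrix(path, "real")
    return ResponseMatrix(cells, drugs, values, ~missing)


def read_feature_table(path: str | Path, kind: str) -> FeatureTable:
    """Read an entity x feature table of the given kind."""
    domain = "binary" if kind in BINARY_KINDS else "real"
    entities, features, values, missing = read_labelled_matrix(path, domain)
    return FeatureTable(entities, features, values, kind, missing)


def read_similarity_matrix(
    path: str | Path, kind: str | None = None, normalized: bool = False
) -> SimilarityMatrix:
    """Read a square labelled similarity matrix (row and column labels must agree)."""
    rows, cols, values, missing = read_labelled_matrix(path, "real")
    if rows != cols:
        raise ParseError(f"{path}: similarity matrix row/column labels disagree")
    if missing.any():
        raise ParseError(f"{path}: similarity matrix contains missing entries")
    return SimilarityMatrix(rows, values, kind, normalized)


def write_labelled_matrix(
    data: ResponseMatrix | FeatureTable | SimilarityMatrix, path: str | Path
) -> None:
    """Write a labelled matrix as TSV/CSV, round-trippable at full precision.

    Missing/unobserved entries are written as "NA"; finite values use
    ``repr`` so that they survive a read/write cycle bit-exactly.
    """
    if isinstance(data, ResponseMatrix):
        row_ids, col_ids = data.cell_ids, data.drug_ids
        values, missing = data.values, ~data.observed_mask
    elif isinstance(data, FeatureTable):
        row_ids, col_ids = data.entity_ids, data.feature_ids
        values, missing = data.values, data.missing_mask
    elif isinstance(data, SimilarityMatrix):
        row_ids, col_ids = data.entity_ids, data.entity_ids
        values = data.values
        missing = np.zeros(values.shape, dtype=bool)
    else:
        raise TypeError(f"cannot serialize {type(data).__name__}")
    write_grid(row_ids, col_ids, values, path, missing)


def write_grid(
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    values: np.ndarray,
    path: str | Path,
    missing_mask: np.ndarray | None = None,
) -> None:
    """Write an arbitrary labelled grid (full-precision, "NA" for missing)."""
    values = np.asarray(values)
    if missing_mask is None:
        missing_mask = np.zeros(values.shape, dtype=bool)
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow([""] + list(col_ids))
        for i, label in enumerate(row_ids):
            writer.writerow(
                [label]
                + [
                    "NA" if missing_mask[i, j] else repr(float(values[i, j]))
                    for j in range(len(col_ids))
                ]
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, then gene labels).

    The description field is ignored; gene order is preserved and
    duplicate genes within one set are collapsed to the first occurrence.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, GMT needs >= 3"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g.strip()))
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na"] + list(genes)) + "\n")


def read_tissue_annotation(path: str | Path) -> TissueAnnotation:
    """Read a two-column (cell, tissue) TSV/CSV with a header row."""
    path = Path(path)
    delim = _delimiter_for(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        rows = [r for r in reader if r]
    for lineno, fields in enumerate(rows[1:], start=2):
        if len(fields) != 2:
            raise ParseError(f"{path}: row {lineno} has {len(fields)} fields, expected 2")
        cell, tissue = fields[0].strip(), fields[1].strip()
        if cell in mapping:
            raise ParseError(f"{path}: duplicate cell label {cell!r} at row {lineno}")
        mapping[cell] = tissue
    return TissueAnnotation(mapping)


def write_tissue_annotation(tissues: TissueAnnotation, path: str | Path) -> None:
    path = Path(path)
    delim = _delimiter_for(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(["cell", "tissue"])
        for cell, tissue in tissues.mapping.items():
            writer.writerow([cell, tissue])
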