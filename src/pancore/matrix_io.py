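"""Tabular I/O: Rtab presence/absence matrices, completeness tables, classification output.

The Rtab dialect is the gene_presence_absence.Rtab convention popularised by
Roary/Panaroo: a header row naming the gene column then one column per
genome, and one row per gene cluster with 0/1 cells. Both tab- and
comma-separated variants are accepted (detected from the header line).
Completeness tables follow the CheckM habit of reporting percentages; values
are normalised to fractions on read.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresenceAbsenceMatrix",
    "CompletenessTable",
    "read_rtab",
    "write_rtab",
    "read_completeness",
    "write_completeness",
    "align_genomes",
    "write_classification",
    "read_classification",
]


class RtabParseError(ValueError):
    """Malformed presence/absence file (ragged row, non-binary cell, ...)."""


@dataclass
class PresenceAbsenceMatrix:
    """Binary gene x genome observation matrix.

    ``values[g, i]`` is 1 when gene cluster ``gene_ids[g]`` was observed in
    genome ``genome_ids[i]``. Gene and genome identifiers are unique and
    ordered; the matrix has at least one gene and one genome.
    """

    gene_ids: list[str]
    genome_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_genomes), dtype uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if len(self.gene_ids) == 0 or len(self.genome_ids) == 0:
            raise ValueError("matrix needs at least 1 gene and 1 genome")
        if self.values.shape != (len(self.gene_ids), len(self.genome_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.genome_ids)} genomes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def reorder_genomes(self, genome_ids: Sequence[str]) -> "PresenceAbsenceMatrix":
        """Permute/subset genome columns; cell values are untouched."""
        index = {g: i for i, g in enumerate(self.genome_ids)}
        missing = [g for g in genome_ids if g not in index]
        if missing:
            raise KeyError(f"genomes not in matrix: {missing}")
        cols = [index[g] for g in genome_ids]
        return PresenceAbsenceMatrix(
            gene_ids=list(self.gene_ids),
            genome_ids=list(genome_ids),
            values=self.values[:, cols].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.genome_ids == other.genome_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class CompletenessTable:
    """Per-genome completeness fractions c_i in (0, 1]."""

    genome_ids: list[str]
    completeness: np.ndarray  # fractions, shape (N,)

    def __post_init__(self) -> None:
        self.completeness = np.asarray(self.completeness, dtype=float)
        if len(self.genome_ids) != self.completeness.size:
            raise ValueError("genome_ids and completeness lengths differ")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome ids")
        if np.any(self.completeness > 1.0) or np.any(self.completeness < 0.0):
            raise ValueError("completeness fractions must lie in [0, 1]")
        if np.any(self.completeness == 0.0):
            zeros = [g for g, c in zip(self.genome_ids, self.completeness) if c == 0.0]
            raise ValueError(
                f"completeness of 0 for {zeros}: a genome contributing nothing "
                "almost surely signals an upstream pipeline failure"
            )

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def subset(self, genome_ids: Sequence[str]) -> "CompletenessTable":
        index = {g: i for i, g in enumerate(self.genome_ids)}
        missing = [g for g in genome_ids if g not in index]
        if missing:
            raise KeyError(f"genomes not in completeness table: {missing}")
        rows = [index[g] for g in genome_ids]
        return CompletenessTable(list(genome_ids), self.completeness[rows].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompletenessTable):
            return NotImplemented
        return self.genome_ids == other.genome_ids and np.allclose(
            self.completeness, other.completeness
        )


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_rtab(path: str | Path) -> PresenceAbsenceMatrix:
    """Read a Roary/Panaroo-style Rtab presence/absence matrix.

    Cells greater than 1 (paralog counts some clusterers emit) are truncated
    to 1 with a warning: the model is presence/absence only.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        first = handle.readline()
        if not first.strip():
            raise RtabParseError(f"{path}: empty file")
        delim = _detect_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        genome_ids = [g.strip() for g in header[1:]]
        if not genome_ids:
            raise RtabParseError(f"{path}: header has no genome columns")
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        truncated = 0
        for lineno, fields in enumerate(csv.reader(handle, delimiter=delim), start=2):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) != len(header):
                raise RtabParseError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0].strip())
            try:
                cells = np.array([int(x) for x in fields[1:]], dtype=np.int64)
            except ValueError as exc:
                raise RtabParseError(
                    f"{path}, line {lineno}: non-integer cell ({exc})"
                ) from None
            if np.any(cells < 0):
                raise RtabParseError(f"{path}, line {lineno}: negative cell value")
            over = cells > 1
            if over.any():
                truncated += int(over.sum())
                cells = np.minimum(cells, 1)
            rows.append(cells.astype(np.uint8))
    if not gene_ids:
        raise ValueError(f"{path}: no gene rows (header only)")
    if truncated:
        warnings.warn(
            f"{path}: truncated {truncated} cell(s) > 1 to presence (paralog "
            "counts are collapsed to presence/absence)",
            stacklevel=2,
        )
    return PresenceAbsenceMatrix(gene_ids, genome_ids, np.vstack(rows))


def write_rtab(
    matrix: PresenceAbsenceMatrix, path: str | Path, gene_column: str = "Gene"
) -> None:
    """Write a matrix in tab-separated Rtab form."""
    df = pd.DataFrame(
        matrix.values, index=pd.Index(matrix.gene_ids, name=gene_column),
        columns=matrix.genome_ids,
    )
    df.to_csv(path, sep="\t")


def read_completeness(
    path: str | Path,
    unit_policy: Literal["auto", "percent", "fraction"] = "auto",
    genome_col: str | None = None,
    completeness_col: str | None = None,
) -> CompletenessTable:
    """Read a genome-completeness table (TSV/CSV, two named columns).

    By default the first column is the genome identifier and the second the
    completeness; pass ``genome_col``/``completeness_col`` to select by
    header name. Under the ``auto`` unit policy any value > 1 in the column
    makes the whole column a percentage (divided by 100), matching CheckM
    output; otherwise values are taken as fractions.
    """
    path = Path(path)
    with path.open() as handle:
        delim = _detect_delimiter(handle.readline())
    df = pd.read_csv(path, sep=delim)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need genome-id and completeness columns")
    gcol = genome_col if genome_col is not None else df.columns[0]
    ccol = completeness_col if completeness_col is not None else df.columns[1]
    for col in (gcol, ccol):
        if col not in df.columns:
            raise ValueError(f"{path}: no column named {col!r}")
    ids = df[gcol].astype(str).str.strip()
    if ids.isna().any() or (ids == "").any():
        raise ValueError(f"{path}: missing genome id")
    values = pd.to_numeric(df[ccol], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna(), gcol].tolist()
        raise ValueError(f"{path}: non-numeric completeness for {bad}")
    values = values.to_numpy(dtype=float)
    if np.any(values < 0.0) or np.any(values > 100.0):
        raise ValueError(f"{path}: completeness values must lie in [0, 100]")
    if unit_policy == "percent" or (unit_policy == "auto" and np.any(values > 1.0)):
        values = values / 100.0
    elif unit_policy not in ("auto", "fraction"):
        raise ValueError(f"unknown unit_policy {unit_policy!r}")
    return CompletenessTable(ids.tolist(), values)


def write_completeness(
    table: CompletenessTable,
    path: str | Path,
    as_percent: bool = False,
    genome_col: str = "genome",
    completeness_col: str = "completeness",
) -> None:
    values = table.completeness * 100.0 if as_percent else table.completeness
    pd.DataFrame({genome_col: table.genome_ids, completeness_col: values}).to_csv(
        path, sep="\t", index=False
    )


def align_genomes(
    matrix: PresenceAbsenceMatrix,
    table: CompletenessTable,
    strictness: Literal["strict", "intersect"] = "strict",
) -> tuple[PresenceAbsenceMatrix, CompletenessTable]:
    """Put matrix columns and completeness rows in the same genome order.

    ``strict`` requires identical genome sets (the safe default: silently
    assuming full completeness for an uncovered genome would bias the
    threshold). ``intersect`` drops genomes absent from either side and
    warns with the count dropped. Purely a permutation/subset operation —
    no cell or completeness value changes.
    """
    mat_set = set(matrix.genome_ids)
    tab_set = set(table.genome_ids)
    if strictness == "strict":
        if mat_set != tab_set:
            only_mat = sorted(mat_set - tab_set)
            only_tab = sorted(tab_set - mat_set)
            raise ValueError(
                "genome sets differ: "
                f"matrix-only={only_mat or 'none'}, completeness-only={only_tab or 'none'}"
            )
        shared = list(matrix.genome_ids)
    elif strictness == "intersect":
        shared = [g for g in matrix.genome_ids if g in tab_set]
        if not shared:
            raise ValueError("genome sets are disjoint: empty intersection")
        dropped = len(mat_set | tab_set) - len(shared)
        if dropped:
            warnings.warn(
                f"align_genomes: dropped {dropped} genome(s) absent from one side",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown strictness {strictness!r}")
    return matrix.reorder_genomes(shared), table.subset(shared)


_CLASSIFICATION_COLUMNS = ["gene_id", "count", "frequency", "label"]
_VALID_LABELS = {"core", "middle", "rare"}


def write_classification(results: Iterable, path: str | Path) -> None:
    """Write per-gene classification records as TSV.

    ``results`` may be GeneClassification objects, mappings, or tuples in
    (gene_id, count, frequency, label) order. Column order is stable and
    counts/labels round-trip losslessly.
    """
    records = []
    for rec in results:
        if hasattr(rec, "gene_id"):
            row = (rec.gene_id, rec.count, rec.frequency, rec.label)
        elif isinstance(rec, dict):
            row = tuple(rec[k] for k in _CLASSIFICATION_COLUMNS)
        else:
            row = tuple(rec)
        if row[3] not in _VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(_VALID_LABELS)}, got {row[3]!r}")
        records.append(row)
    df = pd.DataFrame(records, columns=_CLASSIFICATION_COLUMNS)
    df["count"] = df["count"].astype(int) if len(df) else df["count"]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_classification(path: str | Path) -> pd.DataFrame:
    """Read a classification TSV back into a DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "label": str})
    missing = [c for c in _CLASSIFICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) and not set(df["label"]) <= _VALID_LABELS:
        raise ValueError(f"{path}: invalid labels present")
    return df[_CLASSIFICATION_COLUMNS]
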