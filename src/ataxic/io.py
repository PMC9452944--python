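"""Readers and writers for the plain-text formats the toolkit exchanges.

Supported formats: dense TSV/CSV expression matrices (header row of cell ids,
first column gene ids), MatrixMarket coordinate triplets with sidecar
feature/barcode files, GMT gene-set files, two-column cell -> sample label
tables, and TSV score tables.  All readers validate identifiers strictly and
never reorder genes or cells.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import RAW, CellScoreTable, ExpressionMatrix, GeneSet
from .errors import ParseError, ValidationError

GENES_IN_ROWS = "genes-in-rows"
CELLS_IN_ROWS = "cells-in-rows"

COHORT_SAMPLE = "cohort"


def _sep_for(path: os.PathLike | str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_labels(path: os.PathLike | str) -> dict[str, str]:
    """Read a two-column TSV mapping ``cell_id`` to ``sample_id``.

    A header line is accepted (and skipped) when its first field is
    ``cell_id``; duplicate cell ids are rejected.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            if lineno == 1 and parts[0] == "cell_id":
                continue
            cell, sample = parts
            if cell in labels:
                raise ValidationError(f"{path}: duplicate cell id {cell!r}")
            labels[cell] = sample
    if not labels:
        raise ParseError(f"{path}: no label rows found")
    return labels


def _resolve_labels(
    cell_ids: Sequence[str],
    labels: Mapping[str, str] | os.PathLike | str | None,
) -> dict[str, str]:
    """Attach sample labels; cells absent from an explicit table are rejected."""
    if labels is None:
        return {c: COHORT_SAMPLE for c in cell_ids}
    if not isinstance(labels, Mapping):
        labels = read_labels(labels)
    missing = [c for c in cell_ids if c not in labels]
    if missing:
        raise ValidationError(
            f"{len(missing)} cell(s) have no sample label, e.g. {missing[0]!r}"
        )
    return {c: labels[c] for c in cell_ids}


def read_dense_matrix(
    path: os.PathLike | str,
    orientation: str = GENES_IN_ROWS,
    labels: Mapping[str, str] | os.PathLike | str | None = None,
) -> ExpressionMatrix:
    """Read a dense TSV/CSV matrix into a raw :class:`ExpressionMatrix`.

    The file must have one header row of identifiers and one identifier
    column.  ``orientation`` states what the rows are; the default is
    genes-in-rows, the conventional layout for expression matrices.
    """
    if orientation not in (GENES_IN_ROWS, CELLS_IN_ROWS):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    for ids, kind in ((row_ids, "row"), (col_ids, "column")):
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValidationError(f"{path}: duplicate {kind} id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j in range(df.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.nonzero(pd.isna(col) & ~pd.isna(raw[:, j].astype(object)))[0]
        if pd.isna(col).any():
            i = int(np.nonzero(pd.isna(col))[0][0]) if len(bad) == 0 else int(bad[0])
            raise ParseError(
                f"{path}: non-numeric value {raw[i, j]!r} at row {row_ids[i]!r}, "
                f"column {col_ids[j]!r}"
            )
        values[:, j] = col
    if orientation == CELLS_IN_ROWS:
        values = values.T
        gene_ids, cell_ids = col_ids, row_ids
    else:
        gene_ids, cell_ids = row_ids, col_ids
    return ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        values=values,
        sample_of_cell=_resolve_labels(cell_ids, labels),
        norm_state=RAW,
    )


def write_dense_matrix(mat: ExpressionMatrix, path: os.PathLike | str) -> None:
    """Write a matrix as dense TSV/CSV, genes in rows."""
    mat.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id",
                          float_format="%.17g")


def _read_id_file(path: os.PathLike | str) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if not ids:
        raise ParseError(f"{path}: no identifiers found")
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate identifiers")
    return ids


def read_mtx_triplet(
    matrix_path: os.PathLike | str,
    features_path: os.PathLike | str,
    barcodes_path: os.PathLike | str,
    labels: Mapping[str, str] | os.PathLike | str | None = None,
) -> ExpressionMatrix:
    """Read a MatrixMarket coordinate matrix plus feature/barcode id files.

    Rows are features (genes), columns are barcodes (cells); indices in the
    file are 1-based per the MatrixMarket standard.  Absent entries are zero.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    gene_ids = _read_id_file(features_path)
    cell_ids = _read_id_file(barcodes_path)
    if mat.shape[0] != len(gene_ids):
        raise ValidationError(
            f"matrix has {mat.shape[0]} rows but {features_path} lists "
            f"{len(gene_ids)} features"
        )
    if mat.shape[1] != len(cell_ids):
        raise ValidationError(
            f"matrix has {mat.shape[1]} columns but {barcodes_path} lists "
            f"{len(cell_ids)} barcodes"
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        values=mat,
        sample_of_cell=_resolve_labels(cell_ids, labels),
        norm_state=RAW,
    )


def write_mtx_triplet(
    mat: ExpressionMatrix,
    matrix_path: os.PathLike | str,
    features_path: os.PathLike | str,
    barcodes_path: os.PathLike | str,
) -> None:
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(mat.values))
    Path(features_path).write_text("".join(g + "\n" for g in mat.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in mat.cell_ids))


def read_gmt(path: os.PathLike | str) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...).

    The description column is ignored; duplicate genes within a line are
    deduplicated.  Set order follows file order.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(parts)} fields)"
                )
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, genes=frozenset(genes)))
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: os.PathLike | str,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def write_score_table(table: CellScoreTable, path: os.PathLike | str) -> None:
    """Write a score table as TSV (cell_id, sample_id, score).

    Scores are printed with 17 significant digits so a read-back reproduces
    them to within 1e-12.
    """
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_score_table(path: os.PathLike | str,
                     score_kind: str = "score") -> CellScoreTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    return CellScoreTable(df, score_kind=score_kind)


def write_labels(mat: ExpressionMatrix, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tsample_id\n")
        for c in mat.cell_ids:
            fh.write(f"{c}\t{mat.sample_of_cell[c]}\n")


def read_viability_table(path: os.PathLike | str) -> pd.DataFrame:
    """Read a compound x cell-line viability table (dense TSV, NA allowed)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate compound ids")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate cell-line ids")
    return df.astype(float)
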