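"""Quality-control filters and normalization for scRNA-seq matrices.

The standard pipeline removes, in order: low-complexity cells (fewer than
300 expressed genes), high-mitochondrial cells (mitochondrial expression
above 10% of the cell total), and small samples (patients contributing fewer
than 10 cells after the cell-level filters), then applies the log2(TPM+1)
transform.  All thresholds are strict inequalities: a cell with exactly 300
expressed genes or exactly 10% mitochondrial content is retained, and a
sample with exactly 10 cells is retained.

"Expressed" means strictly positive: the input is a non-negative TPM-like
matrix where zero means undetected.  The mitochondrial fraction is computed
on the raw linear scale, where percent-of-total is meaningful.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .containers import LOG2P1, RAW, ExpressionMatrix, QCReport, QCStep
from .errors import EmptyResultError, StateError

DEFAULT_MIN_GENES = 300
DEFAULT_MAX_MITO_FRAC = 0.10
DEFAULT_MIN_CELLS_PER_SAMPLE = 10
DEFAULT_MITO_PATTERN = r"(?i)^MT-"


def _require_raw(mat: ExpressionMatrix, op: str) -> None:
    if mat.norm_state != RAW:
        raise StateError(f"{op} requires a raw matrix, got norm_state={mat.norm_state!r}")


def _dims(mat: ExpressionMatrix) -> tuple[int, int]:
    return (mat.n_genes, mat.n_cells)


def _apply_cell_filter(
    mat: ExpressionMatrix, keep: np.ndarray, name: str, note: str = ""
) -> tuple[ExpressionMatrix, QCStep]:
    removed = [c for c, k in zip(mat.cell_ids, keep) if not k]
    out = mat.subset_cells(keep)
    if out.n_cells == 0:
        raise EmptyResultError(f"filter {name!r} removed every cell")
    step = QCStep(
        name=name,
        entity_kind="cell",
        n_removed=len(removed),
        dims_before=_dims(mat),
        dims_after=_dims(out),
        removed_ids=removed,
        note=note,
    )
    return out, step


def filter_low_complexity_cells(
    mat: ExpressionMatrix, min_genes: int = DEFAULT_MIN_GENES
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove cells expressing fewer than ``min_genes`` genes (value > 0)."""
    _require_raw(mat, "filter_low_complexity_cells")
    n_expressed = (mat.values > 0).sum(axis=0)
    keep = n_expressed >= min_genes
    out, step = _apply_cell_filter(mat, keep, "low_complexity_cells")
    report = QCReport()
    report.add(step)
    return out, report


def filter_high_mito_cells(
    mat: ExpressionMatrix,
    max_frac: float = DEFAULT_MAX_MITO_FRAC,
    mito_pattern: str = DEFAULT_MITO_PATTERN,
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove cells whose mitochondrial share of total expression exceeds ``max_frac``.

    Cells with zero total expression are removed too, under a distinct
    reason code, since their mitochondrial fraction is undefined.  If the
    pattern matches no genes the matrix is returned unchanged and a warning
    is recorded in the report.
    """
    _require_raw(mat, "filter_high_mito_cells")
    report = QCReport()
    pat = re.compile(mito_pattern)
    is_mito = np.array([bool(pat.search(g)) for g in mat.gene_ids])
    if not is_mito.any():
        report.add(
            QCStep(
                name="high_mito_cells",
                entity_kind="cell",
                n_removed=0,
                dims_before=_dims(mat),
                dims_after=_dims(mat),
                note=f"warning: mito pattern {mito_pattern!r} matched no genes",
            )
        )
        return mat, report
    totals = mat.values.sum(axis=0)
    zero_total = totals == 0
    if zero_total.any():
        mat, step = _apply_cell_filter(
            mat, ~zero_total, "zero_total_expression_cells",
            note="cells with no expression at all; mito fraction undefined",
        )
        report.add(step)
        totals = totals[~zero_total]
    mito_sum = mat.values[is_mito, :].sum(axis=0)
    keep = mito_sum / totals <= max_frac
    out, step = _apply_cell_filter(mat, keep, "high_mito_cells")
    report.add(step)
    return out, report


def filter_small_samples(
    mat: ExpressionMatrix, min_cells: int = DEFAULT_MIN_CELLS_PER_SAMPLE
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop every cell of any sample contributing fewer than ``min_cells`` cells."""
    labels = mat.sample_labels()
    sample_ids, counts = np.unique(labels, return_counts=True)
    small = set(sample_ids[counts < min_cells])
    keep = np.array([s not in small for s in labels])
    out, step = _apply_cell_filter(
        mat, keep, "small_samples",
        note=f"removed samples: {sorted(small)}" if small else "",
    )
    step.entity_kind = "cell"
    report = QCReport()
    report.add(step)
    if small:
        report.add(
            QCStep(
                name="small_samples_sample_count",
                entity_kind="sample",
                n_removed=len(small),
                dims_before=_dims(out),
                dims_after=_dims(out),
                note="sample-level tally of the previous step",
            )
        )
    return out, report


def normalize_log2(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value v by log2(v + 1); mark the matrix as normalized."""
    if mat.norm_state == LOG2P1:
        raise StateError("matrix is already log2(TPM+1)-normalized")
    _require_raw(mat, "normalize_log2")
    return ExpressionMatrix(
        gene_ids=list(mat.gene_ids),
        cell_ids=list(mat.cell_ids),
        values=np.log2(mat.values + 1.0),
        sample_of_cell=dict(mat.sample_of_cell),
        norm_state=LOG2P1,
    )


@dataclass
class QCParams:
    min_genes: int = DEFAULT_MIN_GENES
    max_mito_frac: float = DEFAULT_MAX_MITO_FRAC
    mito_pattern: str = DEFAULT_MITO_PATTERN
    min_cells_per_sample: int = DEFAULT_MIN_CELLS_PER_SAMPLE
    normalize: bool = True


def run_qc_pipeline(
    mat: ExpressionMatrix, params: QCParams | None = None
) -> tuple[ExpressionMatrix, QCReport]:
    """Run the full QC pipeline in canonical order.

    Order: low-complexity filter, mitochondrial filter, small-sample filter,
    then (optionally) log2(v+1) normalization.  The sample filter runs after
    the cell-level filters so a sample is judged on its surviving cells.
    """
    params = params or QCParams()
    report = QCReport()
    mat, rep = filter_low_complexity_cells(mat, params.min_genes)
    report.extend(rep)
    mat, rep = filter_high_mito_cells(mat, params.max_mito_frac, params.mito_pattern)
    report.extend(rep)
    mat, rep = filter_small_samples(mat, params.min_cells_per_sample)
    report.extend(rep)
    if params.normalize:
        mat = normalize_log2(mat)
    return mat, report
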