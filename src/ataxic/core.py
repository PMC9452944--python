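"""The per-cell transcriptomic-perturbation heterogeneity score.

Given a normalized genes x cells matrix, each gene is z-scored across cells
(sample SD, denominator t-1).  A cell's score is then the sample standard
deviation (denominator m'-1) over the m' retained genes of that cell's
absolute z-scores.  A cell whose genes all deviate from their cross-cell
means by equal standardized magnitudes scores 0 (synchronous perturbation);
unequal magnitudes — some genes wildly perturbed, others quiet — raise the
score (asynchronous perturbation).

Genes with zero variance across cells have no defined z-score and are
dropped before scoring; they are reported, never silently imputed.

Scoring scope matters: per-gene means and SDs can be computed within each
sample (patient) independently, or once across a whole cohort.  Both are
supported; the default is per-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    LOG2P1,
    CellScoreTable,
    ExpressionMatrix,
    ZScoreMatrix,
)
from .errors import StateError, ValidationError

SCOPE_SAMPLE = "sample"
SCOPE_COHORT = "cohort"

SCORE_KIND = "tp_heterogeneity"


def gene_zscores(
    mat: ExpressionMatrix, allow_raw: bool = False
) -> tuple[ZScoreMatrix, list[str]]:
    """Standardize each gene across cells; drop zero-variance genes.

    Returns the z-score matrix over the retained genes and the list of
    dropped (constant) genes.  Requires a log2(TPM+1) matrix unless
    ``allow_raw`` is set.
    """
    if mat.norm_state != LOG2P1 and not allow_raw:
        raise StateError(
            "z-scoring expects a log2(TPM+1) matrix; pass allow_raw=True to override"
        )
    t = mat.n_cells
    if t < 2:
        raise ValidationError(f"z-scoring needs at least 2 cells, got {t}")
    means = mat.values.mean(axis=1, keepdims=True)
    sds = mat.values.std(axis=1, ddof=1, keepdims=True)
    retained = (sds[:, 0] > 0) & np.isfinite(sds[:, 0])
    dropped = [g for g, k in zip(mat.gene_ids, retained) if not k]
    if not retained.any() or retained.sum() < 1:
        raise ValidationError("every gene has zero variance; nothing to standardize")
    z = (mat.values[retained] - means[retained]) / sds[retained]
    kept_genes = [g for g, k in zip(mat.gene_ids, retained) if k]
    return ZScoreMatrix(gene_ids=kept_genes, cell_ids=list(mat.cell_ids), z=z), dropped


@dataclass
class ScoreResult:
    """Score table plus the per-group dropped-gene report."""

    table: CellScoreTable
    dropped_genes: dict[str, list[str]] = field(default_factory=dict)


def _score_group(mat: ExpressionMatrix, group: str,
                 allow_raw: bool) -> tuple[np.ndarray, list[str]]:
    if mat.n_cells < 2:
        raise ValidationError(
            f"group {group!r} has {mat.n_cells} cell(s); scoring needs at least 2"
        )
    zmat, dropped = gene_zscores(mat, allow_raw=allow_raw)
    if len(zmat.gene_ids) < 2:
        raise ValidationError(
            f"group {group!r} retains {len(zmat.gene_ids)} gene(s) after "
            "dropping zero-variance genes; scoring needs at least 2"
        )
    scores = np.abs(zmat.z).std(axis=0, ddof=1)
    return scores, dropped


def ataxic_scores(
    mat: ExpressionMatrix,
    scope: str = SCOPE_SAMPLE,
    allow_raw: bool = False,
) -> ScoreResult:
    """Compute the heterogeneity score for every cell.

    With ``scope="sample"`` each sample's cells are z-scored and scored
    independently; with ``scope="cohort"`` the whole matrix is treated as one
    population.  Scores are non-negative; dropped zero-variance genes are
    reported per scope group.
    """
    if scope not in (SCOPE_SAMPLE, SCOPE_COHORT):
        raise ValidationError(f"unknown scoring scope {scope!r}")
    sample_of = mat.sample_of_cell
    score_of: dict[str, float] = {}
    dropped_genes: dict[str, list[str]] = {}
    if scope == SCOPE_COHORT:
        groups = [("cohort", np.ones(mat.n_cells, dtype=bool))]
    else:
        labels = mat.sample_labels()
        groups = [(s, labels == s) for s in mat.samples]
    for group, mask in groups:
        sub = mat if mask.all() else mat.subset_cells(mask)
        scores, dropped = _score_group(sub, group, allow_raw)
        dropped_genes[group] = dropped
        for c, s in zip(sub.cell_ids, scores):
            score_of[c] = float(s)
    table = CellScoreTable.from_arrays(
        cell_ids=list(mat.cell_ids),
        sample_ids=[sample_of[c] for c in mat.cell_ids],
        scores=[score_of[c] for c in mat.cell_ids],
        score_kind=SCORE_KIND,
    )
    return ScoreResult(table=table, dropped_genes=dropped_genes)


def summarize_scores(
    table: CellScoreTable, grouping: str = "sample_id"
) -> pd.DataFrame:
    """Per-group summary: n cells, mean, variation (max - min), sample SD.

    "Variation" is the score range within the group, the spread statistic
    used when comparing heterogeneity levels between cohorts.  Groups with a
    single cell report variation 0 and SD NaN.
    """
    if grouping not in table.frame.columns:
        raise ValidationError(f"no grouping column {grouping!r} in score table")
    rows = []
    for group, sub in table.frame.groupby(grouping, sort=True):
        s = sub["score"].to_numpy(dtype=float)
        rows.append(
            {
                "group": group,
                "n_cells": len(s),
                "mean": float(s.mean()),
                "variation": float(s.max() - s.min()),
                "sd": float(s.std(ddof=1)) if len(s) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
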