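"""Per-cell signature enrichment scoring.

The enrichment score of a gene set in a cell is the arithmetic mean of the
cell's expression values over the set's genes that are present in the
matrix.  This deliberately plain statistic (no ranking, no background
correction) keeps enrichment on the same scale as expression itself.

Gene matching is exact and case-sensitive by default; a case-insensitive
fallback exists because public signature databases disagree on symbol
casing.  Genes absent from the matrix are dropped from the mean (no zero
imputation) and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CellScoreTable, ExpressionMatrix, GeneSet
from .errors import ValidationError


@dataclass
class EnrichmentResult:
    table: CellScoreTable
    n_matched: int
    matched_genes: list[str]
    unmatched_genes: list[str] = field(default_factory=list)


def _match_genes(
    mat: ExpressionMatrix, gs: GeneSet, case_insensitive: bool
) -> tuple[list[int], list[str], list[str]]:
    if case_insensitive:
        index: dict[str, int] = {}
        for i, g in enumerate(mat.gene_ids):
            index.setdefault(g.casefold(), i)
        hits = {g: index.get(g.casefold()) for g in gs.genes}
    else:
        index = {g: i for i, g in enumerate(mat.gene_ids)}
        hits = {g: index.get(g) for g in gs.genes}
    matched = sorted(g for g, i in hits.items() if i is not None)
    unmatched = sorted(g for g, i in hits.items() if i is None)
    rows = sorted({hits[g] for g in matched})  # type: ignore[type-var]
    return rows, matched, unmatched


def enrichment_scores(
    mat: ExpressionMatrix, gs: GeneSet, case_insensitive: bool = False
) -> EnrichmentResult:
    """Mean expression of the set's matched genes, per cell."""
    rows, matched, unmatched = _match_genes(mat, gs, case_insensitive)
    if not rows:
        raise ValidationError(
            f"gene set {gs.name!r} shares no genes with the matrix"
        )
    scores = mat.values[rows, :].mean(axis=0)
    table = CellScoreTable.from_arrays(
        cell_ids=list(mat.cell_ids),
        sample_ids=[mat.sample_of_cell[c] for c in mat.cell_ids],
        scores=scores,
        score_kind=f"enrichment:{gs.name}",
    )
    return EnrichmentResult(
        table=table,
        n_matched=len(rows),
        matched_genes=matched,
        unmatched_genes=unmatched,
    )


@dataclass
class SignatureScores:
    """Cell x signature score matrix plus per-set match diagnostics."""

    frame: pd.DataFrame  # index cell_id, one column per signature
    sample_of_cell: dict[str, str]
    skipped: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def column(self, name: str, score_kind: str | None = None) -> CellScoreTable:
        if name not in self.frame.columns:
            raise ValidationError(f"no signature column {name!r}")
        return CellScoreTable.from_arrays(
            cell_ids=list(self.frame.index),
            sample_ids=[self.sample_of_cell[c] for c in self.frame.index],
            scores=self.frame[name].to_numpy(dtype=float),
            score_kind=score_kind or f"enrichment:{name}",
        )


def score_all_signatures(
    mat: ExpressionMatrix,
    sets: list[GeneSet],
    case_insensitive: bool = False,
) -> SignatureScores:
    """Score every gene set; sets with no matched genes are skipped with a warning.

    Duplicate set names are disambiguated with a deterministic ``.2``, ``.3``
    ... suffix in encounter order.
    """
    if not sets:
        raise ValidationError("no gene sets given")
    columns: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    warnings: list[str] = []
    name_counts: dict[str, int] = {}
    for gs in sets:
        name_counts[gs.name] = name_counts.get(gs.name, 0) + 1
        colname = gs.name if name_counts[gs.name] == 1 else f"{gs.name}.{name_counts[gs.name]}"
        if colname != gs.name:
            warnings.append(f"duplicate set name {gs.name!r} stored as {colname!r}")
        try:
            res = enrichment_scores(mat, gs, case_insensitive=case_insensitive)
        except ValidationError as exc:
            skipped[colname] = str(exc)
            warnings.append(f"skipped {colname!r}: no genes matched")
            continue
        columns[colname] = res.table.scores
    if not columns:
        raise ValidationError("no gene set shares any gene with the matrix")
    frame = pd.DataFrame(columns, index=pd.Index(mat.cell_ids, name="cell_id"))
    return SignatureScores(
        frame=frame,
        sample_of_cell=dict(mat.sample_of_cell),
        skipped=skipped,
        warnings=warnings,
    )
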