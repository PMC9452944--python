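"""In-memory containers shared across the toolkit.

The central object is :class:`ExpressionMatrix`, a dense genes x cells grid of
expression values together with gene/cell identifiers, a cell -> sample
(patient) mapping, and an explicit normalization-state flag.  The flag lets
downstream operations enforce that quality-control filters see raw TPM-like
values while scoring sees log2(TPM+1) values, instead of guessing from the
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

RAW = "raw"
LOG2P1 = "log2p1"
_NORM_STATES = (RAW, LOG2P1)


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {kind} id {dup!r}")


@dataclass
class ExpressionMatrix:
    """Dense genes x cells expression matrix with sample labels.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique row / column identifiers.
    values
        ``(n_genes, n_cells)`` array of finite reals.  Must be non-negative
        while ``norm_state == "raw"`` (TPM-like scale).
    sample_of_cell
        Mapping from every cell id to its sample (patient) id.
    norm_state
        ``"raw"`` or ``"log2p1"``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    sample_of_cell: dict[str, str]
    norm_state: str = RAW

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.sample_of_cell = {str(k): str(v) for k, v in self.sample_of_cell.items()}
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.norm_state not in _NORM_STATES:
            raise ValidationError(f"unknown norm_state {self.norm_state!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        m, t = self.values.shape
        if m != len(self.gene_ids):
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids but {m} value rows"
            )
        if t != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids but {t} value columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        missing = [c for c in self.cell_ids if c not in self.sample_of_cell]
        if missing:
            raise ValidationError(
                f"{len(missing)} cell(s) lack a sample label, e.g. {missing[0]!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")
        if self.norm_state == RAW and np.any(self.values < 0):
            raise ValidationError("raw matrix contains negative values")

    # -- conveniences -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list[str]:
        """Sample ids in order of first appearance among the cells."""
        out: list[str] = []
        seen: set[str] = set()
        for c in self.cell_ids:
            s = self.sample_of_cell[c]
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def sample_labels(self) -> np.ndarray:
        """Per-cell sample label, aligned with ``cell_ids``."""
        return np.array([self.sample_of_cell[c] for c in self.cell_ids])

    def subset_cells(self, keep: np.ndarray | Iterable[bool]) -> "ExpressionMatrix":
        keep = np.asarray(list(keep), dtype=bool)
        kept_cells = [c for c, k in zip(self.cell_ids, keep) if k]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=kept_cells,
            values=self.values[:, keep],
            sample_of_cell={c: self.sample_of_cell[c] for c in kept_cells},
            norm_state=self.norm_state,
        )

    def subset_genes(self, keep: np.ndarray | Iterable[bool]) -> "ExpressionMatrix":
        keep = np.asarray(list(keep), dtype=bool)
        kept_genes = [g for g, k in zip(self.gene_ids, keep) if k]
        return ExpressionMatrix(
            gene_ids=kept_genes,
            cell_ids=list(self.cell_ids),
            values=self.values[keep, :],
            sample_of_cell=dict(self.sample_of_cell),
            norm_state=self.norm_state,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ZScoreMatrix:
    """Per-gene standardized expression: zero mean, unit sample SD per row."""

    gene_ids: list[str]
    cell_ids: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("z shape does not match identifiers")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("z contains non-finite entries")


@dataclass
class CellScoreTable:
    """One real-valued score per cell (heterogeneity or enrichment score)."""

    frame: pd.DataFrame  # columns: cell_id, sample_id, score
    score_kind: str = "score"

    REQUIRED = ("cell_id", "sample_id", "score")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValidationError(f"score table missing column {col!r}")
        self.frame = self.frame.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        if self.frame["cell_id"].duplicated().any():
            dup = self.frame["cell_id"][self.frame["cell_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate cell id {dup!r} in score table")
        if len(self.frame) and not np.all(np.isfinite(self.frame["score"].to_numpy(float))):
            raise ValidationError("score table contains non-finite scores")

    @classmethod
    def from_arrays(
        cls,
        cell_ids: Sequence[str],
        sample_ids: Sequence[str],
        scores: Sequence[float],
        score_kind: str = "score",
    ) -> "CellScoreTable":
        return cls(
            pd.DataFrame(
                {"cell_id": list(cell_ids), "sample_id": list(sample_ids),
                 "score": np.asarray(scores, dtype=float)}
            ),
            score_kind=score_kind,
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy(dtype=float)

    @property
    def cell_ids(self) -> list[str]:
        return self.frame["cell_id"].tolist()

    def score_of(self) -> Mapping[str, float]:
        return dict(zip(self.frame["cell_id"], self.frame["score"]))


@dataclass(frozen=True)
class GeneSet:
    """Named collection of gene identifiers (marker signature or pathway)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))


@dataclass
class QCStep:
    """One filter application: what ran, what it removed, shape before/after."""

    name: str
    entity_kind: str  # "cell" | "sample" | "gene"
    n_removed: int
    dims_before: tuple[int, int]  # (genes, cells)
    dims_after: tuple[int, int]
    removed_ids: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if self.n_removed < 0:
            raise ValidationError("removal count cannot be negative")


@dataclass
class QCReport:
    """Ordered record of quality-control filtering."""

    steps: list[QCStep] = field(default_factory=list)

    def add(self, step: QCStep) -> None:
        if self.steps and step.dims_before != self.steps[-1].dims_after:
            raise ValidationError(
                "QC step dimensions are inconsistent with the previous step"
            )
        self.steps.append(step)

    def extend(self, other: "QCReport") -> None:
        for step in other.steps:
            self.add(step)

    def total_removed(self, entity_kind: str = "cell") -> int:
        return sum(s.n_removed for s in self.steps if s.entity_kind == entity_kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.name,
                    "entity_kind": s.entity_kind,
                    "n_removed": s.n_removed,
                    "genes_before": s.dims_before[0],
                    "cells_before": s.dims_before[1],
                    "genes_after": s.dims_after[0],
                    "cells_after": s.dims_after[1],
                    "note": s.note,
                }
                for s in self.steps
            ]
        )
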