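from __future__ import annotations

import numpy as np
import pytest

from ataxic.containers import ExpressionMatrix


def make_matrix(values, norm_state="log2p1", sample=None, gene_ids=None,
                cell_ids=None) -> ExpressionMatrix:
    """Build a matrix with auto-generated ids and one sample unless given."""
    values = np.asarray(values, dtype=float)
    m, t = values.shape
    gene_ids = gene_ids or [f"G{i + 1}" for i in range(m)]
    cell_ids = cell_ids or [f"c{j + 1}" for j in range(t)]
    if sample is None:
        sample = {c: "S1" for c in cell_ids}
    elif isinstance(sample, (list, tuple)):
        sample = dict(zip(cell_ids, sample))
    return ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        values=values,
        sample_of_cell=sample,
        norm_state=norm_state,
    )


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """The worked 3-gene x 3-cell example: one constant gene among three."""
    return make_matrix(
        [[1.0, 2.0, 3.0], [2.0, 2.0, 2.0], [0.0, 1.0, 5.0]],
        gene_ids=["G1", "G2", "G3"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
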