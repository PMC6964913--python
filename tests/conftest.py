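"""Shared fixtures: seeded synthetic datasets reused across modules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crosstalk import (
    CountMatrix,
    demo_design,
    generate_dataset,
    interaction_study_design,
    log_normalize,
    qc_normalize,
)

DEMO_SEED = 0
STUDY_SEED = 1


@pytest.fixture(scope="session")
def demo_data():
    """Default demo experiment: matrix, annotation, truth ledger."""
    return generate_dataset(demo_design(seed=DEMO_SEED))


@pytest.fixture(scope="session")
def demo_processed(demo_data):
    """QC-filtered + normalized demo data: (matrix, annotation,
    normalized matrix, QC report)."""
    m, ann, _ = demo_data
    return qc_normalize(m, ann)


@pytest.fixture(scope="session")
def study_data():
    """Interaction-recovery design: 2 planted gains + 2 planted losses
    for the serotonin comparison."""
    return generate_dataset(interaction_study_design(seed=STUDY_SEED))


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 cells with a hand-checkable pattern."""
    counts = np.array(
        [
            [5, 0, 2, 0],
            [1, 1, 1, 1],
            [0, 3, 0, 0],
        ]
    )
    return CountMatrix(["ga", "gb", "mt-nd1"], ["c1", "c2", "c3", "c4"], sp.csc_matrix(counts))


def make_normalized(values, gene_ids=None, cell_ids=None):
    """Build a NormalizedMatrix directly from a dense (genes x cells)
    array of already-log values (for tests that engineer statistics)."""
    from crosstalk import NormalizedMatrix

    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(gene_ids, cell_ids, sp.csc_matrix(values))
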