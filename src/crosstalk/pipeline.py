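"""End-to-end convenience wrappers used by the analysis drivers, the
acceptance checks and the CLI examples.
"""

from __future__ import annotations

import pandas as pd

from .interactions import build_interaction_graph, classify_differential, cluster_expression_profile
from .io import CountMatrix, DifferentialEdge, InteractionEdge
from .preprocess import QCThresholds, compute_cell_qc, filter_cells_genes, log_normalize


def qc_normalize(m: CountMatrix, annotation: pd.DataFrame, thresholds: QCThresholds | None = None):
    """QC-filter, align the annotation, and log-normalize.

    Returns (filtered matrix, aligned annotation, normalized matrix,
    QC report).
    """
    qc = compute_cell_qc(m)
    filtered, report = filter_cells_genes(m, qc, thresholds)
    ann = annotation.loc[filtered.cell_ids]
    return filtered, ann, log_normalize(filtered), report


def per_condition_edges(
    m: CountMatrix,
    annotation: pd.DataFrame,
    lr: pd.DataFrame,
    cluster_col: str = "cluster",
    condition_col: str = "condition",
    min_frac: float = 0.1,
    min_cells_expr: int = 3,
) -> dict[str, list[InteractionEdge]]:
    """Ligand-receptor edge list per condition.

    Each condition's cells are normalized and profiled independently so
    a condition's edges depend only on its own cells.
    """
    edges: dict[str, list[InteractionEdge]] = {}
    genes = sorted(set(lr["ligand"]) | set(lr["receptor"]))
    for cond in pd.unique(annotation[condition_col]):
        keep = (annotation[condition_col] == cond).to_numpy()
        sub = m.subset_cells(keep)
        nm = log_normalize(sub)
        profile = cluster_expression_profile(sub, nm, annotation.loc[keep, cluster_col], genes)
        edges[cond] = build_interaction_graph(
            profile, lr, min_frac=min_frac, min_cells_expr=min_cells_expr, condition=str(cond)
        )
    return edges


def differential_maps(
    edges: dict[str, list[InteractionEdge]],
    control: str,
    treatments: list[str] | None = None,
) -> dict[str, list[DifferentialEdge]]:
    """Classify each treatment's edges against the control condition."""
    if treatments is None:
        treatments = [c for c in edges if c != control]
    return {
        t: classify_differential(edges[control], edges[t], (t, control)) for t in treatments
    }
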