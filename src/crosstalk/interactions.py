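"""Per-condition ligand-receptor interaction graphs and their
treatment-vs-control classification.

A cluster "expresses" a gene when at least ``min_frac`` of its cells
(and at least ``min_cells_expr`` cells) have a nonzero count.  An edge
(A, L, R, B) is asserted for a condition when cluster A expresses the
ligand L and cluster B expresses its cognate receptor R; self-edges are
admitted.  Comparing the control and treatment edge sets partitions
their union into unchanged / lost / gained edges — the three arrow
colors of a differential interaction map.

Edges are presence/absence calls, not weighted scores; the mean
normalized expression of both endpoints is carried as an auxiliary
annotation only.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, DifferentialEdge, InteractionEdge, NormalizedMatrix, validate_lr_table

log = logging.getLogger(__name__)


def cluster_expression_profile(
    m: CountMatrix,
    nm: NormalizedMatrix,
    clusters,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (cluster, gene): number and fraction of expressing cells and
    mean normalized expression.

    ``genes`` restricts the profile (typically to the ligand-receptor
    universe); genes absent from the matrix are reported with zero
    expression so that pair tables mentioning unmeasured genes do not
    crash the graph stage.  Every cell must carry a cluster label.
    """
    clusters = pd.Series(np.asarray(clusters), index=m.cell_ids)
    if clusters.isna().any() or (clusters.astype(str) == "").any():
        raise ValueError("unlabeled cells in cluster vector")
    genes = list(dict.fromkeys(genes)) if genes is not None else list(m.gene_ids)
    rows = []
    cluster_order = sorted(clusters.astype(str).unique())
    for cl in cluster_order:
        idx = np.flatnonzero((clusters.astype(str) == cl).to_numpy())
        n = idx.size
        for g in genes:
            try:
                gi = m.gene_index(g)
            except KeyError:
                rows.append((cl, g, n, 0, 0.0, 0.0))
                continue
            counts = np.asarray(m.counts[gi, idx].todense()).ravel()
            norm = np.asarray(nm.values[nm.gene_index(g), idx].todense()).ravel()
            n_expr = int((counts > 0).sum())
            rows.append((cl, g, n, n_expr, n_expr / n, float(norm.mean())))
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "n_cells", "n_expressing", "frac_expressing", "mean_norm"]
    ).set_index(["cluster", "gene"])


def build_interaction_graph(
    profile: pd.DataFrame,
    lr: pd.DataFrame,
    min_frac: float = 0.1,
    min_cells_expr: int = 3,
    direction: str = "ligand_anchored",
    anchor: str | None = None,
    condition: str = "",
) -> list[InteractionEdge]:
    """Emit every (source, ligand, receptor, target) edge whose two
    endpoints pass the cluster-expression rule.

    ``ligand_anchored`` with an anchor gene keeps the pairs whose ligand
    is the anchor (all receptors of that ligand); ``receptor_anchored``
    keeps the pairs whose receptor is the anchor (all ligands of that
    receptor).  Without an anchor all pairs are used.
    """
    lr = validate_lr_table(lr)
    if direction not in ("ligand_anchored", "receptor_anchored"):
        raise ValueError(f"unknown direction {direction!r}")
    if anchor is not None:
        col = "ligand" if direction == "ligand_anchored" else "receptor"
        lr = lr[lr[col] == anchor]
        if lr.empty:
            raise ValueError(f"anchor gene {anchor!r} not found as {col} in the pair table")
    expressing: dict[str, set[str]] = {}
    mean_norm: dict[tuple[str, str], float] = {}
    for (cl, gene), row in profile.iterrows():
        ok = row["frac_expressing"] >= min_frac and row["n_expressing"] >= min_cells_expr
        if ok:
            expressing.setdefault(gene, set()).add(cl)
        mean_norm[(cl, gene)] = row["mean_norm"]
    edges = []
    for lig, rec in lr.itertuples(index=False):
        for a in sorted(expressing.get(lig, ())):
            for b in sorted(expressing.get(rec, ())):
                edges.append(InteractionEdge(a, lig, rec, b, condition))
    return sorted(edges)


def classify_differential(
    control_edges: Sequence[InteractionEdge],
    treatment_edges: Sequence[InteractionEdge],
    comparison: tuple[str, str],
) -> list[DifferentialEdge]:
    """Partition the union of both edge sets by fate.

    unchanged = present in both; lost = control only; gained = treatment
    only.  Deterministic and independent of input order.
    """
    treatment, control = comparison
    c = {e.key() for e in control_edges}
    t = {e.key() for e in treatment_edges}
    out = []
    for key in sorted(c | t):
        if key in c and key in t:
            status = "unchanged"
        elif key in c:
            status = "lost"
        else:
            status = "gained"
        out.append(DifferentialEdge(*key, status=status, treatment=treatment, control=control))
    return out


def rank_target_clusters(diff_edges: Sequence[DifferentialEdge]) -> pd.DataFrame:
    """Incoming-edge counts per target cluster, split by status.

    Sorted by total in-degree descending — the clusters with the most
    arrows pointing at them come first.
    """
    if not diff_edges:
        return pd.DataFrame(columns=["unchanged", "lost", "gained", "total"])
    df = pd.DataFrame(
        [(e.target_cluster, e.status) for e in diff_edges], columns=["target_cluster", "status"]
    )
    table = df.pivot_table(index="target_cluster", columns="status", aggfunc="size", fill_value=0)
    for col in ("unchanged", "lost", "gained"):
        if col not in table.columns:
            table[col] = 0
    table = table[["unchanged", "lost", "gained"]]
    table.columns.name = None
    table["total"] = table.sum(axis=1)
    return table.sort_values(["total", "target_cluster"], ascending=[False, True], kind="mergesort")
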