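"""Receptor-defined subpopulation overlap and gene-set statistics.

Two receptor-positive subpopulations (positivity = raw count > 0) are
compared over the union of cells positive for at least one of the two
genes, yielding only-A / only-B / both counts and percentages.  DEG-list
overlap uses the same union denominator.  Over-representation of a
study gene set against named gene sets is the one-sided hypergeometric
upper-tail test with BH-FDR reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix


@dataclass
class SubpopulationOverlap:
    """Counts and union-percentages of two positive subpopulations."""

    gene_a: str
    gene_b: str
    n_only_a: int
    n_only_b: int
    n_both: int

    @property
    def n_union(self) -> int:
        return self.n_only_a + self.n_only_b + self.n_both

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_union if self.n_union else 0.0

    @property
    def pct_only_a(self) -> float:
        return self._pct(self.n_only_a)

    @property
    def pct_only_b(self) -> float:
        return self._pct(self.n_only_b)

    @property
    def pct_both(self) -> float:
        return self._pct(self.n_both)


def receptor_overlap(
    m: CountMatrix, gene_a: str, gene_b: str, cell_scope=None
) -> SubpopulationOverlap:
    """Overlap of the ``gene_a``-positive and ``gene_b``-positive cells.

    Percentages are over the union of cells positive for at least one of
    the two genes, restricted to ``cell_scope`` when given (e.g. only
    the progenitor clusters).
    """
    if cell_scope is not None:
        scope_idx = m.cell_indices(cell_scope)
        if scope_idx.size == 0:
            raise ValueError("empty cell scope")
    else:
        scope_idx = np.arange(m.n_cells)
    a = m.gene_counts(gene_a)[scope_idx] > 0
    b = m.gene_counts(gene_b)[scope_idx] > 0
    return SubpopulationOverlap(
        gene_a,
        gene_b,
        n_only_a=int((a & ~b).sum()),
        n_only_b=int((b & ~a).sum()),
        n_both=int((a & b).sum()),
    )


def deg_overlap(genes_a, genes_b) -> dict:
    """Set overlap of two DEG lists with the union as denominator."""
    a = set(genes_a)
    b = set(genes_b)
    union = a | b
    common = a & b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
        "n_common": len(common),
        "n_union": len(union),
        "pct_common_of_union": 100.0 * len(common) / len(union) if union else 0.0,
    }


def hypergeometric_ora(
    study,
    collection: dict[str, set],
    universe,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test.

    For each named set: overlap k with the study set (size n) drawn from
    a universe of N genes containing K set members; p = P(X >= k).
    Returns one row per set with p, BH-FDR and the significance flag at
    ``p_max`` on the raw p.
    """
    universe = set(universe)
    study = set(study)
    stray = sorted(study - universe)
    if stray:
        raise ValueError(f"study genes outside the universe: {stray[:10]}")
    if any(not name for name in collection):
        raise ValueError("empty gene-set name in collection")
    n_univ = len(universe)
    n_study = len(study)
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        k = len(study & members)
        K = len(members)
        p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_study)) if K else 1.0
        expected = n_study * K / n_univ if n_univ else 0.0
        rows.append(
            {
                "set": name,
                "n_set": K,
                "n_study": n_study,
                "n_overlap": k,
                "expected": expected,
                "fold_enrichment": (k / expected) if expected else np.nan,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p"] < p_max
        out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return out
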