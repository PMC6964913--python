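"""Receptor-positive dissection and thresholded differential expression.

The statistic pair is the two-sided Wilcoxon rank-sum p-value and the
average log fold change on the natural-log scale,

    avg_logFC = ln(mean(expm1(x1)) + 1) - ln(mean(expm1(x2)) + 1),

computed on log-normalized expression with pseudocount 1 on the
de-logged group means.  DEGs are retained at raw p < 0.05 and
|avg_logFC| >= 0.25 with no multiple-testing correction at this stage;
the marker stage applies BH-FDR separately.

Subpopulation "dissection" selects the cells with nonzero raw count of
a named receptor gene (htr1d+, il4r.1+, ngfra+ ...), optionally within
a cell-type scope, before differential testing.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "p", "avg_logFC", "pct_1", "pct_2", "comparison", "subpopulation"]


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For combined sample sizes up to 12 without ties the exact null
    distribution is used; otherwise the normal approximation with tie
    and continuity corrections.  Complete ties give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0
    no_ties = len(np.unique(combined)) == combined.size
    method = "exact" if (no_ties and combined.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def rank_sum_pvalues(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p per column of two (cells x genes)
    blocks, asymptotic with tie and continuity corrections.

    Columns where every value (both groups pooled) is identical get
    p = 1.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[0] == 0 or x2.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(x1, x2, alternative="two-sided", method="asymptotic", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    pooled = np.concatenate([x1, x2], axis=0)
    degenerate = np.ptp(pooled, axis=0) == 0
    p = np.where(np.isnan(p) | degenerate, 1.0, p)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def _avg_logfc_block(x1: np.ndarray, x2: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    m1 = np.expm1(x1).mean(axis=0)
    m2 = np.expm1(x2).mean(axis=0)
    return np.log(m1 + pseudocount) - np.log(m2 + pseudocount)


def average_log_fc(
    nm: NormalizedMatrix,
    group1,
    group2,
    gene: str,
    pseudocount: float = 1.0,
) -> float:
    """Natural-log fold change between de-logged group means for one gene."""
    i1 = nm.cell_indices(group1)
    i2 = nm.cell_indices(group2)
    if i1.size == 0 or i2.size == 0:
        raise ValueError("both groups must be nonempty")
    g = nm.gene_index(gene)
    row = np.asarray(nm.values[g, :].todense()).ravel()
    return float(
        np.log(np.expm1(row[i1]).mean() + pseudocount) - np.log(np.expm1(row[i2]).mean() + pseudocount)
    )


# ---------------------------------------------------------------------------
# dissection
# ---------------------------------------------------------------------------


def select_positive_cells(
    m: CountMatrix, gene: str, cell_scope=None
) -> tuple[list[str], list[str]]:
    """Cells with nonzero raw count of ``gene`` and their complement.

    ``cell_scope`` (an iterable of cell ids) restricts both sets; the
    complement is the scope minus the positives.
    """
    counts = m.gene_counts(gene)
    if cell_scope is None:
        scope_idx = np.arange(m.n_cells)
    else:
        scope_idx = m.cell_indices(cell_scope)
    pos_mask = counts[scope_idx] > 0
    positives = [m.cell_ids[i] for i in scope_idx[pos_mask]]
    complement = [m.cell_ids[i] for i in scope_idx[~pos_mask]]
    if not positives:
        warnings.warn(f"no cells positive for {gene!r} in the given scope")
    return positives, complement


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------


def de_table(
    nm: NormalizedMatrix,
    group1,
    group2,
    min_pct: float = 0.1,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Test every gene expressed in >= ``min_pct`` of either group.

    Returns one row per tested gene: p, avg_logFC, pct_1, pct_2.  Small
    comparisons (n1 + n2 <= 12) go through the scalar test so the exact
    path applies; larger ones use the vectorized normal approximation.
    """
    i1 = nm.cell_indices(group1)
    i2 = nm.cell_indices(group2)
    if i1.size == 0 or i2.size == 0:
        raise ValueError("both groups must be nonempty")
    x1 = nm.dense_cells_by_genes(i1)
    x2 = nm.dense_cells_by_genes(i2)
    pct1 = (x1 > 0).mean(axis=0)
    pct2 = (x2 > 0).mean(axis=0)
    tested = np.flatnonzero(np.maximum(pct1, pct2) >= min_pct) if min_pct > 0 else np.arange(nm.n_genes)
    if i1.size + i2.size <= 12:
        p = np.array([rank_sum_test(x1[:, j], x2[:, j]) for j in tested])
    else:
        p = rank_sum_pvalues(x1[:, tested], x2[:, tested])
    lfc = _avg_logfc_block(x1[:, tested], x2[:, tested], pseudocount)
    return pd.DataFrame(
        {
            "gene": [nm.gene_ids[j] for j in tested],
            "p": p,
            "avg_logFC": lfc,
            "pct_1": pct1[tested],
            "pct_2": pct2[tested],
        }
    )


def find_degs(
    nm: NormalizedMatrix,
    group1,
    group2,
    p_max: float = 0.05,
    lfc_min: float = 0.25,
    min_cells: int = 3,
    min_pct: float = 0.1,
    comparison: tuple[str, str] | None = None,
    subpopulation: str = "all",
) -> pd.DataFrame:
    """Thresholded DEG list between two cell groups.

    Keeps genes with p < ``p_max`` and |avg_logFC| >= ``lfc_min``,
    sorted by |avg_logFC| descending (ties broken by gene symbol).  Both
    groups must contain at least ``min_cells`` cells.
    """
    g1 = list(group1)
    g2 = list(group2)
    if len(g1) < min_cells or len(g2) < min_cells:
        raise ValueError(
            f"each group needs at least {min_cells} cells "
            f"(got {len(g1)} and {len(g2)})"
        )
    table = de_table(nm, g1, g2, min_pct=min_pct)
    keep = (table["p"] < p_max) & (table["avg_logFC"].abs() >= lfc_min)
    out = table[keep].copy()
    out["abs_lfc"] = out["avg_logFC"].abs()
    out = out.sort_values(["abs_lfc", "gene"], ascending=[False, True], kind="mergesort")
    out = out.drop(columns="abs_lfc").reset_index(drop=True)
    if comparison is not None:
        out["comparison"] = f"{comparison[0]}_vs_{comparison[1]}"
    else:
        out["comparison"] = ""
    out["subpopulation"] = subpopulation
    return out


def reciprocal_genes(table_a: pd.DataFrame, table_b: pd.DataFrame) -> list[str]:
    """Genes present in both DEG tables with opposite-signed avg_logFC."""
    a = table_a.set_index("gene")["avg_logFC"]
    b = table_b.set_index("gene")["avg_logFC"]
    common = a.index.intersection(b.index)
    flipped = common[(a.loc[common] * b.loc[common]) < 0]
    return sorted(flipped)
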