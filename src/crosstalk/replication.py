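"""Re-derive headline counts from supplementary DEG spreadsheets.

Published single-cell studies often ship their DEG lists as XLSX
supplements whose column headers vary (gene vs Gene vs symbol, logFC vs
avg_logFC vs log2FC, p_val vs pvalue ...).  This stage loads such a
table, auto-detects the identifier / fold-change / p-value columns by
header heuristics, and re-derives directional counts, unique-gene
counts (optionally re-applying the p and |logFC| filters) and pairwise
overlaps through the same code paths the synthetic pipeline uses.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .overlap import deg_overlap

log = logging.getLogger(__name__)

# case-insensitive header candidates, in priority order
GENE_HEADERS = ["gene", "genes", "gene_symbol", "symbol", "gene_id", "geneid", "ensembl", "id", "name"]
LFC_HEADERS = ["avg_logfc", "logfc", "log2fc", "log2foldchange", "avg_log2fc", "foldchange", "fc"]
P_HEADERS = ["p_val", "pval", "p", "pvalue", "p_value"]
FDR_HEADERS = ["p_val_adj", "padj", "fdr", "qval", "q_value", "adj_p"]


def _match_column(columns, candidates) -> str | None:
    lowered = {str(c).strip().lower(): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    # substring fallback (e.g. "avg_logFC (natural log)")
    for cand in candidates:
        for low, orig in lowered.items():
            if cand in low:
                return orig
    return None


def read_supplementary_table(path, sheet=0) -> pd.DataFrame:
    """Load a DEG table from XLSX/TSV/CSV with standardized columns.

    Output columns: ``gene`` plus whichever of ``log_fc``, ``p``,
    ``fdr`` could be identified.  The detected header mapping is logged.
    If no identifier column is named, the first column is assumed to
    hold gene identifiers.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    mapping = {}
    gene_col = _match_column(df.columns, GENE_HEADERS)
    if gene_col is None:
        gene_col = df.columns[0]
        log.warning("%s: no recognizable gene column; using first column %r", path.name, gene_col)
    mapping[gene_col] = "gene"
    lfc_col = _match_column([c for c in df.columns if c != gene_col], LFC_HEADERS)
    if lfc_col is not None:
        mapping[lfc_col] = "log_fc"
    fdr_col = _match_column([c for c in df.columns if c not in mapping], FDR_HEADERS)
    if fdr_col is not None:
        mapping[fdr_col] = "fdr"
    p_col = _match_column([c for c in df.columns if c not in mapping], P_HEADERS)
    if p_col is not None:
        mapping[p_col] = "p"
    log.info("%s: column mapping %s", path.name, mapping)
    out = df.rename(columns=mapping)[list(mapping.values())].copy()
    out["gene"] = out["gene"].astype(str)
    for col in ("log_fc", "p", "fdr"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def count_directional(table: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down): rows with positive / negative fold change."""
    if "log_fc" not in table.columns:
        raise ValueError(
            "no fold-change-like column detected; recognized headers include "
            + ", ".join(LFC_HEADERS)
        )
    lfc = table["log_fc"].dropna()
    return int((lfc > 0).sum()), int((lfc < 0).sum())


def count_degs(
    table: pd.DataFrame, p_max: float | None = None, lfc_min: float | None = None
) -> int:
    """Number of unique genes, optionally after re-applying filters.

    ``p_max`` filters on the p column (falling back to FDR if only that
    is present); ``lfc_min`` on |log_fc|.  With both None the table is
    counted as shipped.
    """
    df = table
    if p_max is not None:
        col = "p" if "p" in df.columns else ("fdr" if "fdr" in df.columns else None)
        if col is None:
            raise ValueError("no p-value column available for filtering")
        df = df[df[col] < p_max]
    if lfc_min is not None:
        if "log_fc" not in df.columns:
            raise ValueError("no fold-change column available for filtering")
        df = df[df["log_fc"].abs() >= lfc_min]
    return int(df["gene"].nunique())


def overlap_report(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Unique-gene overlap of two tables via the shared set arithmetic."""
    return deg_overlap(table_a["gene"].unique(), table_b["gene"].unique())
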