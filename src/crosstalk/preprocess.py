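"""Cell/gene quality control, log-normalization and variable genes.

QC keeps cells with 1,000-15,000 UMIs, 500-2,500 detected genes and at
most 6% mitochondrial counts (all bounds inclusive and overridable),
then drops genes detected in fewer than 5 remaining cells.  Expression
is log-normalized as ln(1 + 1e4 * count / cell total).  Variable genes
are ranked per sample by binned standardized dispersion and the top
1,000 per sample are merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Inclusive per-cell bounds and the per-gene detection floor.

    The UMI/gene windows read the stated ranges as closed intervals;
    mito_max is a fraction of counts, not of genes.
    """

    umi_min: int = 1000
    umi_max: int = 15000
    genes_min: int = 500
    genes_max: int = 2500
    mito_max: float = 0.06
    min_cells_per_gene: int = 5

    def __post_init__(self) -> None:
        if self.umi_min > self.umi_max:
            raise ValueError("umi_min > umi_max")
        if self.genes_min > self.genes_max:
            raise ValueError("genes_min > genes_max")
        if not (0.0 <= self.mito_max <= 1.0):
            raise ValueError("mito_max must lie in [0, 1]")


def compute_cell_qc(m: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell QC metrics: n_umi, n_genes, pct_mito.

    pct_mito is the fraction of the cell's counts on genes whose symbol
    starts with ``mito_prefix``; a cell with zero total gets pct_mito 0
    and is flagged in the ``zero_total`` column.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty matrix")
    totals = m.cell_totals().astype(float)
    n_genes = m.genes_per_cell()
    mt_mask = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
    if mt_mask.any():
        mito = np.asarray(m.counts[mt_mask, :].sum(axis=0)).ravel().astype(float)
    else:
        mito = np.zeros(m.n_cells)
    zero = totals == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(zero, 0.0, mito / np.where(zero, 1.0, totals))
    return pd.DataFrame(
        {
            "n_umi": totals.astype(int),
            "n_genes": n_genes.astype(int),
            "pct_mito": pct,
            "zero_total": zero,
        },
        index=pd.Index(m.cell_ids, name="cell_id"),
    )


def filter_cells_genes(
    m: CountMatrix, qc: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, dict[str, int]]:
    """Apply the cell window and the gene detection floor.

    Returns the filtered matrix plus a report of how many cells each
    rule removed (rules evaluated on the input, removal is the AND of
    all three) and how many genes fell under the detection floor among
    the surviving cells.
    """
    t = thresholds or QCThresholds()
    qc = qc.loc[m.cell_ids]
    umi_ok = (qc["n_umi"] >= t.umi_min) & (qc["n_umi"] <= t.umi_max)
    genes_ok = (qc["n_genes"] >= t.genes_min) & (qc["n_genes"] <= t.genes_max)
    mito_ok = qc["pct_mito"] <= t.mito_max
    keep_cells = (umi_ok & genes_ok & mito_ok).to_numpy()
    filtered = m.subset_cells(keep_cells)
    detected = filtered.cells_per_gene()
    keep_genes = detected >= t.min_cells_per_gene
    # a gene detected nowhere is also below any positive floor
    out = filtered.subset_genes(keep_genes)
    report = {
        "n_cells_in": m.n_cells,
        "n_cells_fail_umi": int((~umi_ok).sum()),
        "n_cells_fail_genes": int((~genes_ok).sum()),
        "n_cells_fail_mito": int((~mito_ok).sum()),
        "n_cells_kept": out.n_cells,
        "n_genes_in": m.n_genes,
        "n_genes_removed": int((~keep_genes).sum()),
        "n_genes_kept": out.n_genes,
    }
    log.info("QC filter: %s", report)
    return out, report


def log_normalize(m: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """ln(1 + scale_factor * count / cell total), sparsity preserved.

    Cells must have nonzero totals (filter first).
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("all-zero cells present; run QC filtering before normalization")
    x = m.counts.astype(np.float64).tocsc(copy=True)
    # scale each column by scale_factor / total
    scale = scale_factor / totals
    x.data *= np.repeat(scale, np.diff(x.indptr))
    np.log1p(x.data, out=x.data)
    return NormalizedMatrix(list(m.gene_ids), list(m.cell_ids), x, scale_factor)


def _dispersion_z(nm: NormalizedMatrix, cell_idx: np.ndarray, n_bins: int = 20) -> pd.DataFrame:
    """Per-gene mean and binned standardized dispersion.

    Dispersion is var/mean of expm1(normalized value); genes are placed
    in equal-frequency bins of the mean and the dispersion is z-scored
    within each bin.
    """
    sub = nm.values[:, cell_idx]
    expm1 = sub.copy()
    expm1.data = np.expm1(expm1.data)
    n = len(cell_idx)
    mean = np.asarray(expm1.sum(axis=1)).ravel() / n
    sq = expm1.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.sum(axis=1)).ravel() / n
    var = np.maximum(ex2 - mean**2, 0.0) * (n / max(n - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    df = pd.DataFrame({"gene": nm.gene_ids, "mean": mean, "dispersion": disp})
    expressed = df["mean"] > 0
    if expressed.sum() == 0:
        df["z"] = 0.0
        return df
    # with very few genes, equal-frequency bins would hold one gene each
    # and every z-score would collapse to zero; cap the bin count so each
    # bin keeps several genes
    n_bins = min(n_bins, max(1, int(expressed.sum()) // 10))
    ranks = df.loc[expressed, "mean"].rank(method="first")
    bins = np.ceil(ranks / (len(ranks) / n_bins)).clip(1, n_bins).astype(int)
    z = pd.Series(0.0, index=df.index)
    grouped = df.loc[expressed, "dispersion"].groupby(bins)
    mu = grouped.transform("mean")
    sd = grouped.transform("std").fillna(0.0)
    zz = (df.loc[expressed, "dispersion"] - mu) / sd.replace(0.0, np.inf)
    z.loc[expressed] = zz.fillna(0.0)
    df["z"] = z
    return df


def select_variable_genes(
    nm: NormalizedMatrix,
    sample_labels: pd.Series | None = None,
    top_n: int = 1000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Top ``top_n`` variable genes per sample, merged.

    Returns one row per selected gene with the samples that selected it
    (comma-joined) and the best (highest) standardized dispersion seen.
    With ``top_n`` above the number of expressed genes all of them are
    returned with a warning.
    """
    if sample_labels is None:
        sample_labels = pd.Series(["all"] * nm.n_cells, index=nm.cell_ids)
    else:
        if len(sample_labels) != nm.n_cells:
            raise ValueError("sample_labels length does not match the number of cells")
        sample_labels = pd.Series(np.asarray(sample_labels), index=nm.cell_ids)
    selected: dict[str, dict] = {}
    for sample in sorted(sample_labels.unique()):
        cell_idx = np.flatnonzero((sample_labels == sample).to_numpy())
        stats = _dispersion_z(nm, cell_idx, n_bins=n_bins)
        expressed = stats[stats["mean"] > 0]
        k = top_n
        if k > len(expressed):
            warnings.warn(
                f"top_n={top_n} exceeds the {len(expressed)} expressed genes in sample {sample!r}; "
                "returning all of them"
            )
            k = len(expressed)
        top = expressed.nlargest(k, "z")
        for gene, zval in zip(top["gene"], top["z"]):
            rec = selected.setdefault(gene, {"gene": gene, "samples": [], "z": -np.inf})
            rec["samples"].append(sample)
            rec["z"] = max(rec["z"], float(zval))
    out = pd.DataFrame(
        [
            {"gene": r["gene"], "n_samples": len(r["samples"]), "samples": ",".join(r["samples"]), "z": r["z"]}
            for r in selected.values()
        ]
    )
    if out.empty:
        return pd.DataFrame(columns=["gene", "n_samples", "samples", "z"])
    return out.sort_values(["n_samples", "z"], ascending=False, kind="mergesort").reset_index(drop=True)
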