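"""Quality control and normalization of the simulated experiment.

Applies the droplet QC window (1,000-15,000 UMIs, 500-2,500 genes,
<= 6% mitochondrial counts, genes detected in >= 5 cells), then
log-normalizes (ln(1 + 1e4 * count/total)) and reports the per-sample
top-1,000 variable-gene union.  Writes the filtered triplet, per-cell
QC metrics and the filter report to results/qc/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosstalk import compute_cell_qc, filter_cells_genes, log_normalize, write_mtx_triplet
from crosstalk.io import read_cell_table, read_mtx_triplet, write_cell_table
from crosstalk.preprocess import select_variable_genes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    indir = args.outdir / "synthetic"
    m = read_mtx_triplet(indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv")
    ann = read_cell_table(indir / "cells.tsv")

    qc = compute_cell_qc(m)
    filtered, report = filter_cells_genes(m, qc)
    outdir = args.outdir / "qc"
    write_mtx_triplet(filtered, outdir)
    write_cell_table(ann.loc[filtered.cell_ids], outdir / "cells.tsv")
    qc.loc[filtered.cell_ids].rename_axis("cell_id").reset_index().to_csv(
        outdir / "qc_metrics.tsv", sep="\t", index=False
    )
    pd.Series(report).rename_axis("metric").to_frame("value").to_csv(outdir / "qc_report.tsv", sep="\t")

    nm = log_normalize(filtered)
    variable = select_variable_genes(nm, ann.loc[filtered.cell_ids, "sample_id"], top_n=1000)
    variable.to_csv(outdir / "variable_genes.tsv", sep="\t", index=False)

    print(f"cells: {report['n_cells_in']} -> {report['n_cells_kept']} "
          f"(UMI window removed {report['n_cells_fail_umi']}, gene window {report['n_cells_fail_genes']}, "
          f"mito cap {report['n_cells_fail_mito']})")
    print(f"genes: {report['n_genes_in']} -> {report['n_genes_kept']} "
          f"({report['n_genes_removed']} under the 5-cell floor)")
    print(f"variable-gene union across samples: {len(variable)} genes")


if __name__ == "__main__":
    main()
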