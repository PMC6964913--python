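"""DEGs in the dissected htr1d+ subpopulation and reciprocal ligands.

Cells with nonzero htr1d counts are dissected from the rest, then
differential expression (rank-sum p < 0.05, |avg_logFC| >= 0.25) is run
for serotonin vs control and IL4 vs control.  Ligands (from the demo
pair table) appearing in both DEG tables with opposite-signed fold
changes are the reciprocally regulated candidates — bdnf, nrg1 and igf1
by construction of the simulation.  Writes the DEG tables, the ligand
subsets and the reciprocal list to results/deg/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crosstalk import find_degs, log_normalize, reciprocal_genes, select_positive_cells
from crosstalk.io import read_cell_table, read_mtx_triplet
from crosstalk.sim import demo_lr_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    indir = args.outdir / "qc"
    m = read_mtx_triplet(indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv")
    ann = read_cell_table(indir / "cells.tsv")
    nm = log_normalize(m)

    positives, _ = select_positive_cells(m, "htr1d")
    pos = ann.loc[positives]
    outdir = args.outdir / "deg"
    outdir.mkdir(parents=True, exist_ok=True)

    ligands = sorted(set(demo_lr_table()["ligand"]))
    tables = {}
    for treatment in ("5HT", "il4"):
        degs = find_degs(
            nm,
            pos.index[pos["condition"] == treatment].tolist(),
            pos.index[pos["condition"] == "control"].tolist(),
            comparison=(treatment, "control"),
            subpopulation="htr1d+ cells",
        )
        degs.to_csv(outdir / f"degs_htr1d_{treatment}_vs_control.tsv", sep="\t", index=False)
        lig = degs[degs["gene"].isin(ligands)]
        lig.to_csv(outdir / f"ligand_degs_{treatment}_vs_control.tsv", sep="\t", index=False)
        tables[treatment] = degs
        print(f"{treatment} vs control in htr1d+ cells: {len(degs)} DEGs, "
              f"{len(lig)} of them ligands {sorted(lig['gene'])}")

    recip = reciprocal_genes(tables["5HT"], tables["il4"])
    recip_ligands = sorted(set(recip) & set(ligands))
    pd.DataFrame({"gene": recip, "is_ligand": [g in ligands for g in recip]}).to_csv(
        outdir / "reciprocal_genes.tsv", sep="\t", index=False
    )
    print(f"genes changing reciprocally between serotonin and IL4: {len(recip)}; "
          f"reciprocal ligands: {recip_ligands}")


if __name__ == "__main__":
    main()
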