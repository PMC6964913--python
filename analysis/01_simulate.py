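"""Generate the demo multi-condition dataset with ground truth.

Five populations (htr1d+ neurons, progenitor clusters PC0 and PC2,
immune cells, oligodendrocytes) under four conditions (control, amyloid,
IL4, serotonin).  Serotonin silences neuronal bdnf (losing the bdnf
edges into the progenitors); amyloid/IL4 switch on il4r.1 in the
progenitors (gaining the il4 edges); three neuronal ligands (bdnf,
nrg1, igf1) change reciprocally between the serotonin and IL4 arms.

Writes the MatrixMarket triplet, the cell table and the truth ledger to
results/synthetic/.
"""

import argparse
from pathlib import Path

from crosstalk import demo_design, generate_dataset, write_fixture


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    design = demo_design(seed=args.seed)
    matrix, annotation, truth = generate_dataset(design)
    outdir = args.outdir / "synthetic"
    write_fixture(matrix, annotation, truth, outdir)

    print(f"seed {args.seed}: {matrix.n_genes} genes x {matrix.n_cells} cells "
          f"({len(design.cell_types)} populations x {len(design.conditions)} conditions)")
    for cond in design.conditions[1:]:
        print(f"  truth {cond} vs control: {len(truth.gained[cond])} gained, "
              f"{len(truth.lost[cond])} lost edges")
    print(f"wrote fixture to {outdir}")


if __name__ == "__main__":
    main()
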