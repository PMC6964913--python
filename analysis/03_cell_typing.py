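"""Marker detection and label transfer into the serotonin sample.

The reference (control, amyloid and IL4 samples, with their true
population labels) yields one-vs-rest markers per cluster; the top-5
positive markers per cluster (FDR < 0.1) train a 500-tree random
forest, which then predicts the cell types of the serotonin sample.
Accuracy is evaluated against the simulator's ground truth.  Writes
markers, top markers and predicted labels to results/cell_typing/.
"""

import argparse
from pathlib import Path

from crosstalk import find_markers, log_normalize, predict_labels, top_markers, train_label_transfer
from crosstalk.io import read_cell_table, read_mtx_triplet


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    indir = args.outdir / "qc"
    m = read_mtx_triplet(indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv")
    ann = read_cell_table(indir / "cells.tsv")

    ref_mask = (ann["condition"] != "5HT").to_numpy()
    m_ref = m.subset_cells(ref_mask)
    m_query = m.subset_cells(~ref_mask)
    nm_ref = log_normalize(m_ref)

    markers = find_markers(nm_ref, ann.loc[ref_mask, "cluster"])
    top = top_markers(markers, top_k=5)
    model = train_label_transfer(nm_ref, ann.loc[ref_mask, "cluster"], seed=args.seed, markers=markers)
    pred = predict_labels(model, log_normalize(m_query))

    outdir = args.outdir / "cell_typing"
    outdir.mkdir(parents=True, exist_ok=True)
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
    top.to_csv(outdir / "top_markers.tsv", sep="\t", index=False)
    pred.reset_index().to_csv(outdir / "predicted_labels.tsv", sep="\t", index=False)

    truth = ann.loc[~ref_mask, "cluster"]
    acc = float((pred["label"].to_numpy() == truth.to_numpy()).mean())
    print(f"{markers['cluster'].nunique()} clusters, {len(top)} top markers, "
          f"{len(model.feature_genes)} classifier features")
    print(f"serotonin-sample label transfer: {len(pred)} cells, "
          f"accuracy vs ground truth {acc:.3f}")


if __name__ == "__main__":
    main()
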