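"""Marker detection and classifier-based cell-type label transfer.

Each cluster is tested one-vs-rest with the shared rank-sum / avg_logFC
machinery; BH-FDR is applied within each cluster's test family and
markers are called at FDR < 0.1.  Label transfer trains a random forest
(500 trees, class-balanced bootstrap) on the union of each reference
cluster's top-5 positive markers and predicts query cells from their
normalized expression over those features, so query samples inherit the
reference partition without being re-clustered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .diffexpr import de_table
from .io import NormalizedMatrix

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["cluster", "gene", "avg_logFC", "p", "fdr", "pct_in", "pct_out"]


def find_markers(
    nm: NormalizedMatrix,
    clusters,
    min_cells: int = 3,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest marker table over all clusters.

    Clusters with fewer than ``min_cells`` cells are skipped with a
    warning; a single usable cluster is an error because there is no
    "rest" to compare against.
    """
    clusters = pd.Series(np.asarray(clusters), index=nm.cell_ids)
    sizes = clusters.value_counts()
    usable = sizes[sizes >= min_cells].index.tolist()
    skipped = sizes[sizes < min_cells].index.tolist()
    if skipped:
        warnings.warn(f"clusters below {min_cells} cells skipped: {skipped}")
    if len(usable) < 2:
        raise ValueError("marker detection needs at least two clusters with enough cells")
    frames = []
    for cl in sorted(map(str, usable)):
        in_cells = clusters.index[clusters.astype(str) == cl].tolist()
        out_cells = clusters.index[clusters.astype(str) != cl].tolist()
        table = de_table(nm, in_cells, out_cells, min_pct=min_pct)
        if table.empty:
            continue
        table = table.rename(columns={"pct_1": "pct_in", "pct_2": "pct_out"})
        table.insert(0, "cluster", cl)
        # BH over the cluster's whole test family, then keep the
        # positive-marker direction: elevated fraction or fold change
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        positive = (table["pct_in"] > table["pct_out"]) | (table["avg_logFC"] > 0)
        frames.append(table.loc[positive, MARKER_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def top_markers(markers: pd.DataFrame, top_k: int = 5, fdr_max: float = 0.1) -> pd.DataFrame:
    """Top ``top_k`` positive markers per cluster at FDR < ``fdr_max``.

    Only positively elevated genes qualify (identity features); ranking
    is by avg_logFC descending, then p ascending, then gene symbol.
    """
    eligible = markers[(markers["fdr"] < fdr_max) & (markers["avg_logFC"] > 0)].copy()
    eligible = eligible.sort_values(
        ["cluster", "avg_logFC", "p", "gene"], ascending=[True, False, True, True], kind="mergesort"
    )
    return eligible.groupby("cluster", sort=True).head(top_k).reset_index(drop=True)


@dataclass
class LabelTransferModel:
    """Fitted ensemble and the marker features it reads."""

    feature_genes: list[str]
    classifier: RandomForestClassifier
    classes: list[str]
    seed: int

    def feature_matrix(self, nm: NormalizedMatrix) -> np.ndarray:
        """Dense (cells x features) block; absent genes are imputed as 0
        with a warning."""
        cols = []
        missing = []
        zeros = np.zeros(nm.n_cells)
        for g in self.feature_genes:
            try:
                idx = nm.gene_index(g)
            except KeyError:
                missing.append(g)
                cols.append(zeros)
                continue
            cols.append(np.asarray(nm.values[idx, :].todense()).ravel())
        if missing:
            warnings.warn(f"feature genes absent from query, imputed as 0: {missing}")
        return np.column_stack(cols)


def train_label_transfer(
    nm_ref: NormalizedMatrix,
    clusters,
    top_k: int = 5,
    seed: int = 0,
    n_estimators: int = 500,
    markers: pd.DataFrame | None = None,
) -> LabelTransferModel:
    """Train the label-transfer forest on a labeled reference.

    Features are the union over clusters of the ``top_k`` positive
    markers at FDR < 0.1.  A precomputed marker table may be passed to
    avoid re-testing.  Deterministic for a fixed seed.
    """
    clusters = pd.Series(np.asarray(clusters).astype(str), index=nm_ref.cell_ids)
    if clusters.nunique() < 2:
        raise ValueError("label transfer needs at least two reference classes")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if markers is None:
        markers = find_markers(nm_ref, clusters)
    top = top_markers(markers, top_k=top_k)
    empty = sorted(set(clusters.unique()) - set(top["cluster"].unique()))
    if empty:
        warnings.warn(
            f"clusters with no qualifying markers (still trained as classes): {empty}"
        )
    features = sorted(top["gene"].unique())
    if not features:
        raise ValueError("no cluster yielded any qualifying marker gene")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        class_weight="balanced_subsample",
        random_state=seed,
        n_jobs=1,
    )
    model = LabelTransferModel(features, clf, sorted(clusters.unique()), seed)
    clf.fit(model.feature_matrix(nm_ref), clusters.to_numpy())
    return model


def predict_labels(model: LabelTransferModel, nm_query: NormalizedMatrix) -> pd.DataFrame:
    """Per-cell predicted label and ensemble vote fraction.

    Cells whose whole feature vector is zero are flagged ``all_zero``;
    their label is whatever the forest's majority vote produces and
    their confidence is typically low.
    """
    if nm_query.n_cells == 0:
        return pd.DataFrame(columns=["label", "confidence", "all_zero"])
    x = model.feature_matrix(nm_query)
    proba = model.classifier.predict_proba(x)
    labels = model.classifier.classes_[np.argmax(proba, axis=1)]
    return pd.DataFrame(
        {
            "label": labels,
            "confidence": proba.max(axis=1),
            "all_zero": (x == 0).all(axis=1),
        },
        index=pd.Index(nm_query.cell_ids, name="cell_id"),
    )
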