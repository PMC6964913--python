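"""Cluster expression profiles, edge rules, differential classification."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crosstalk import (
    CountMatrix,
    InteractionEdge,
    build_interaction_graph,
    classify_differential,
    cluster_expression_profile,
    log_normalize,
    rank_target_clusters,
)


def profile_frame(rows):
    """rows: (cluster, gene, n_cells, n_expressing, mean_norm)"""
    return pd.DataFrame(
        [
            {
                "cluster": c,
                "gene": g,
                "n_cells": n,
                "n_expressing": k,
                "frac_expressing": k / n,
                "mean_norm": m,
            }
            for c, g, n, k, m in rows
        ]
    ).set_index(["cluster", "gene"])


LR = pd.DataFrame([("L", "R"), ("L2", "R")], columns=["ligand", "receptor"])


class TestProfile:
    def test_fraction_arithmetic(self):
        dense = np.zeros((2, 10), dtype=int)
        dense[0, :4] = 3  # gene g0 in 4 of 10 cells
        dense[1, :] = 1
        m = CountMatrix(["g0", "g1"], [f"c{j}" for j in range(10)], sp.csc_matrix(dense))
        prof = cluster_expression_profile(m, log_normalize(m), ["A"] * 10)
        assert prof.loc[("A", "g0"), "frac_expressing"] == pytest.approx(0.4)
        assert prof.loc[("A", "g0"), "n_expressing"] == 4

    def test_absent_gene_zero(self):
        dense = np.ones((1, 4), dtype=int)
        m = CountMatrix(["g0"], [f"c{j}" for j in range(4)], sp.csc_matrix(dense))
        prof = cluster_expression_profile(m, log_normalize(m), ["A"] * 4, genes=["g0", "ghost"])
        assert prof.loc[("A", "ghost"), "frac_expressing"] == 0

    def test_single_cell_cluster_frac_binary(self):
        dense = np.array([[1, 0], [1, 1]])
        m = CountMatrix(["g0", "g1"], ["c0", "c1"], sp.csc_matrix(dense))
        prof = cluster_expression_profile(m, log_normalize(m), ["A", "B"])
        assert set(prof["frac_expressing"]) <= {0.0, 1.0}

    def test_unlabeled_cells_rejected(self):
        dense = np.ones((1, 2), dtype=int)
        m = CountMatrix(["g0"], ["c0", "c1"], sp.csc_matrix(dense))
        with pytest.raises(ValueError, match="unlabeled"):
            cluster_expression_profile(m, log_normalize(m), ["A", None])


class TestBuildGraph:
    def test_edge_emitted(self):
        prof = profile_frame([("A", "L", 10, 5, 1.0), ("B", "R", 10, 3, 1.0)])
        edges = build_interaction_graph(prof, LR, min_frac=0.1, min_cells_expr=3)
        assert [e.key() for e in edges] == [("A", "L", "R", "B")]

    def test_below_min_frac_no_edge(self):
        prof = profile_frame([("A", "L", 10, 5, 1.0), ("B", "R", 100, 5, 1.0)])
        assert build_interaction_graph(prof, LR, min_frac=0.1) == []

    def test_below_min_cells_no_edge(self):
        prof = profile_frame([("A", "L", 10, 5, 1.0), ("B", "R", 4, 2, 1.0)])
        assert build_interaction_graph(prof, LR, min_frac=0.1, min_cells_expr=3) == []

    def test_self_edge_admitted(self):
        prof = profile_frame([("A", "L", 10, 5, 1.0), ("A", "R", 10, 5, 1.0)])
        edges = build_interaction_graph(prof, LR)
        assert ("A", "L", "R", "A") in [e.key() for e in edges]

    def test_receptor_anchor_selects_all_ligands(self):
        prof = profile_frame(
            [("A", "L", 10, 5, 1.0), ("A", "L2", 10, 5, 1.0), ("B", "R", 10, 5, 1.0)]
        )
        edges = build_interaction_graph(prof, LR, direction="receptor_anchored", anchor="R")
        assert {e.ligand for e in edges} == {"L", "L2"}

    def test_unknown_anchor_rejected(self):
        prof = profile_frame([("A", "L", 10, 5, 1.0)])
        with pytest.raises(ValueError, match="anchor gene"):
            build_interaction_graph(prof, LR, anchor="nope")

    def test_min_frac_monotone(self):
        rng = np.random.default_rng(0)
        rows = []
        for c in "ABCD":
            for g in ("L", "L2", "R"):
                k = int(rng.integers(0, 11))
                rows.append((c, g, 10, k, 1.0))
        prof = profile_frame(rows)
        sizes = []
        for mf in (0.05, 0.1, 0.3, 0.6, 0.9):
            sizes.append(len(build_interaction_graph(prof, LR, min_frac=mf, min_cells_expr=0)))
        assert sizes == sorted(sizes, reverse=True)


def edge(*key):
    return InteractionEdge(*key)


class TestClassify:
    def test_set_identities(self):
        e1 = edge("A", "L", "R", "B")
        e2 = edge("A", "L2", "R", "B")
        both = classify_differential([e1], [e1], ("t", "c"))
        assert [(d.status, d.key()) for d in both] == [("unchanged", e1.key())]
        lost = classify_differential([e1], [], ("t", "c"))
        assert lost[0].status == "lost"
        gained = classify_differential([], [e2], ("t", "c"))
        assert gained[0].status == "gained"

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        universe = [edge(a, l, "R", b) for a in "AB" for l in ("L", "L2") for b in "AB"]
        for _ in range(20):
            c = [e for e in universe if rng.random() < 0.5]
            t = [e for e in universe if rng.random() < 0.5]
            diff = classify_differential(c, t, ("t", "c"))
            keys = [d.key() for d in diff]
            assert len(keys) == len(set(keys))  # each edge exactly once
            assert set(keys) == {e.key() for e in c} | {e.key() for e in t}
            for d in diff:
                in_c = d.key() in {e.key() for e in c}
                in_t = d.key() in {e.key() for e in t}
                expected = "unchanged" if (in_c and in_t) else ("lost" if in_c else "gained")
                assert d.status == expected

    def test_order_independence(self):
        c = [edge("A", "L", "R", "B"), edge("B", "L", "R", "A")]
        t = [edge("A", "L", "R", "B")]
        assert classify_differential(c, t, ("t", "c")) == classify_differential(c[::-1], t, ("t", "c"))


class TestRankTargets:
    def test_counting(self):
        diffs = classify_differential(
            [], [edge("A", "L", "R", "PC0"), edge("B", "L", "R", "PC0"), edge("B", "L2", "R", "PC0"), edge("A", "L", "R", "PC2")],
            ("t", "c"),
        )
        table = rank_target_clusters(diffs)
        assert list(table.index) == ["PC0", "PC2"]
        assert table.loc["PC0", "gained"] == 3
        assert table.loc["PC0", "total"] == 3

    def test_empty(self):
        assert rank_target_clusters([]).empty

    def test_planted_gains_concentrate_on_progenitors(self, study_data):
        from crosstalk import per_condition_edges, qc_normalize

        m, ann, truth = study_data
        filtered, annf, _, _ = qc_normalize(m, ann)
        from crosstalk.sim import demo_lr_table

        edges = per_condition_edges(filtered, annf, demo_lr_table())
        diff = classify_differential(edges["control"], edges["5HT"], ("5HT", "control"))
        changed = [d for d in diff if d.status != "unchanged"]
        table = rank_target_clusters(changed)
        assert set(table.index[:2]) == {"PC0", "PC2"}
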