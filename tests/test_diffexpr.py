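"""Rank-sum test, fold change, dissection and DEG thresholds."""

import numpy as np
import pytest
import scipy.sparse as sp

from crosstalk import (
    CountMatrix,
    average_log_fc,
    find_degs,
    generate_dataset,
    log_normalize,
    rank_sum_test,
    reciprocal_genes,
    select_positive_cells,
    two_group_design,
)
from crosstalk.diffexpr import de_table

from conftest import make_normalized


def permutation_pvalue(x, y, n_perm, rng):
    """Independent Monte-Carlo oracle for the two-sided rank-sum test:
    fraction of random group relabelings whose rank statistic deviates
    from its null mean by at least as much as the observed one."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    mean = n1 * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mean)
    perm = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    stat = np.abs(perm[:, :n1].sum(axis=1) - mean)
    return float((stat >= obs - 1e-9).mean())


class TestRankSum:
    def test_exact_small_case(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_complete_ties(self):
        assert rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_large_shift_significant_and_matches_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 100)
        y = rng.normal(2, 1, 100)
        p = rank_sum_test(x, y)
        assert p < 1e-6
        assert permutation_pvalue(x, y, 10**5, rng) <= 3.0 / 10**5  # oracle sees (almost) nothing as extreme

    def test_asymptotic_close_to_permutation_with_ties(self):
        # moderate-n discrete data: the tie-corrected normal
        # approximation should track the permutation oracle closely
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.integers(0, 5, 25).astype(float)
            y = rng.integers(0, 6, 30).astype(float)
            p = rank_sum_test(x, y)
            p_hat = permutation_pvalue(x, y, 10**5, rng)
            se = np.sqrt(max(p_hat * (1 - p_hat), 1e-12) / 10**5)
            assert abs(p - p_hat) <= 0.01 + 3 * se


class TestAvgLogFC:
    def test_identical_groups_zero(self):
        nm = make_normalized(np.log(2) * np.ones((1, 6)))
        assert average_log_fc(nm, ["c0", "c1", "c2"], ["c3", "c4", "c5"], "g0") == pytest.approx(0.0)

    def test_direct_evaluation(self):
        vals = np.zeros((1, 6))
        vals[0, :3] = np.log(2)  # expm1 -> 1
        nm = make_normalized(vals)
        lfc = average_log_fc(nm, ["c0", "c1", "c2"], ["c3", "c4", "c5"], "g0")
        assert lfc == pytest.approx(np.log(2))

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        nm = make_normalized(rng.uniform(0, 2, size=(1, 8)))
        g1, g2 = [f"c{j}" for j in range(4)], [f"c{j}" for j in range(4, 8)]
        assert average_log_fc(nm, g1, g2, "g0") == pytest.approx(-average_log_fc(nm, g2, g1, "g0"))

    def test_absent_gene(self):
        nm = make_normalized(np.ones((1, 2)))
        with pytest.raises(KeyError, match="nope"):
            average_log_fc(nm, ["c0"], ["c1"], "nope")


class TestDissection:
    def matrix(self):
        dense = np.array([[1, 0, 2, 0], [0, 0, 0, 0], [1, 1, 1, 1]])
        return CountMatrix(["htr1d", "silent", "gb"], ["c1", "c2", "c3", "c4"], sp.csc_matrix(dense))

    def test_positive_and_complement(self):
        pos, rest = select_positive_cells(self.matrix(), "htr1d")
        assert pos == ["c1", "c3"] and rest == ["c2", "c4"]

    def test_scope_restriction(self):
        pos, rest = select_positive_cells(self.matrix(), "htr1d", cell_scope=["c1", "c2"])
        assert pos == ["c1"] and rest == ["c2"]

    def test_all_zero_gene_warns(self):
        with pytest.warns(UserWarning, match="no cells positive"):
            pos, rest = select_positive_cells(self.matrix(), "silent")
        assert pos == []

    def test_absent_gene_named_in_error(self):
        with pytest.raises(KeyError, match="ngfra"):
            select_positive_cells(self.matrix(), "ngfra")


class TestFindDEGs:
    def engineered_nm(self):
        # 3 genes x 60 cells (30 per group) with controlled shifts:
        # g_big: strong shift, |lfc| well above 0.25 -> retained
        # g_small: clear shift but |lfc| ~ 0.18 -> excluded on lfc
        # g_null: identical distributions -> excluded on p
        rng = np.random.default_rng(2)
        n = 30
        base = rng.uniform(0.9, 1.1, size=n)
        vals = np.zeros((3, 2 * n))
        vals[0, :n] = np.log1p(np.expm1(base) * 2.2)
        vals[0, n:] = base
        vals[1, :n] = np.log1p(np.expm1(base) * 1.25)
        vals[1, n:] = base
        vals[2, :n] = base
        vals[2, n:] = base
        return make_normalized(vals, gene_ids=["g_big", "g_small", "g_null"])

    def groups(self):
        return [f"c{j}" for j in range(30)], [f"c{j}" for j in range(30, 60)]

    def test_joint_threshold(self):
        nm = self.engineered_nm()
        g1, g2 = self.groups()
        table = de_table(nm, g1, g2, min_pct=0)
        assert table.set_index("gene").loc["g_small", "p"] < 0.05
        assert abs(table.set_index("gene").loc["g_small", "avg_logFC"]) < 0.25
        degs = find_degs(nm, g1, g2, min_pct=0)
        assert list(degs["gene"]) == ["g_big"]

    def test_min_cells_rule_cited(self):
        nm = self.engineered_nm()
        with pytest.raises(ValueError, match="at least 3 cells"):
            find_degs(nm, ["c0", "c1"], ["c2", "c3", "c4"])

    def test_cell_order_invariance(self):
        nm = self.engineered_nm()
        g1, g2 = self.groups()
        rng = np.random.default_rng(0)
        a = find_degs(nm, g1, g2, min_pct=0)
        b = find_degs(nm, rng.permutation(g1).tolist(), rng.permutation(g2).tolist(), min_pct=0)
        assert a.equals(b)

    def test_null_data_few_retained(self):
        d = two_group_design(n_genes=1000, n_cells=100, mean=2.0, seed=21)
        m, ann, _ = generate_dataset(d)
        nm = log_normalize(m)
        degs = find_degs(
            nm,
            ann.index[ann["condition"] == "treated"].tolist(),
            ann.index[ann["condition"] == "control"].tolist(),
            min_pct=0,
        )
        # joint p/lfc filter keeps well under 5% of null genes
        assert len(degs) / 1000 < 0.05

    def test_comparison_labels(self):
        nm = self.engineered_nm()
        g1, g2 = self.groups()
        degs = find_degs(nm, g1, g2, min_pct=0, comparison=("5HT", "control"), subpopulation="htr1d+")
        assert (degs["comparison"] == "5HT_vs_control").all()
        assert (degs["subpopulation"] == "htr1d+").all()


class TestReciprocal:
    def table(self, pairs):
        import pandas as pd

        return pd.DataFrame(pairs, columns=["gene", "avg_logFC"])

    def test_opposite_sign_found(self):
        assert reciprocal_genes(self.table([("g1", 0.5)]), self.table([("g1", -0.4)])) == ["g1"]

    def test_same_sign_not(self):
        assert reciprocal_genes(self.table([("g1", 0.5)]), self.table([("g1", 0.4)])) == []

    def test_disjoint_tables_empty(self):
        assert reciprocal_genes(self.table([("g1", 0.5)]), self.table([("g2", -0.4)])) == []
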