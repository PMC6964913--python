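"""QC arithmetic, filter rules, normalization, variable genes."""

import numpy as np
import pytest
import scipy.sparse as sp

from crosstalk import CountMatrix, QCThresholds, compute_cell_qc, filter_cells_genes, log_normalize
from crosstalk.preprocess import select_variable_genes


def matrix_from_dense(dense, genes=None, cells=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{j}" for j in range(dense.shape[1])]
    return CountMatrix(genes, cells, sp.csc_matrix(dense))


class TestCellQC:
    def test_arithmetic(self):
        m = matrix_from_dense([[5], [5]], genes=["ga", "mt-nd1"])
        qc = compute_cell_qc(m)
        assert qc.loc["c0", "n_umi"] == 10
        assert qc.loc["c0", "n_genes"] == 2
        assert qc.loc["c0", "pct_mito"] == 0.5

    def test_no_mito_genes(self):
        m = matrix_from_dense([[5], [5]], genes=["ga", "gb"])
        assert (compute_cell_qc(m)["pct_mito"] == 0).all()

    def test_all_zero_cell_flagged(self):
        m = matrix_from_dense([[5, 0], [1, 0]])
        qc = compute_cell_qc(m)
        assert qc.loc["c1", "n_umi"] == 0
        assert qc.loc["c1", "pct_mito"] == 0
        assert bool(qc.loc["c1", "zero_total"])


class TestFilter:
    def cells_with_totals(self, totals, n_genes=20):
        # spread each total over n_genes so the gene window is inert
        cols = []
        for t in totals:
            base = np.full(n_genes, t // n_genes)
            base[: t % n_genes] += 1
            cols.append(base)
        return matrix_from_dense(np.array(cols).T)

    def test_umi_bounds_inclusive(self):
        m = self.cells_with_totals([999, 1000, 15000, 15001])
        t = QCThresholds(umi_min=1000, umi_max=15000, genes_min=1, genes_max=10**6, mito_max=1.0, min_cells_per_gene=0)
        out, report = filter_cells_genes(m, compute_cell_qc(m), t)
        assert out.cell_ids == ["c1", "c2"]
        assert report["n_cells_fail_umi"] == 2

    def test_mito_rule(self):
        # cell c1 at 7% mito is removed under the default 6% cap
        dense = np.zeros((21, 2), dtype=int)
        dense[:20, 0] = 50
        dense[:20, 1] = 50
        dense[20, 0] = int(1000 * 0.05 / 0.95)  # ~5%
        dense[20, 1] = int(round(1000 * 0.07 / 0.93))  # ~7%
        genes = [f"g{i}" for i in range(20)] + ["mt-nd1"]
        m = matrix_from_dense(dense, genes=genes)
        t = QCThresholds(umi_min=0, umi_max=10**6, genes_min=0, genes_max=10**6, min_cells_per_gene=0)
        out, report = filter_cells_genes(m, compute_cell_qc(m), t)
        assert out.cell_ids == ["c0"]
        assert report["n_cells_fail_mito"] == 1

    def test_gene_detection_floor(self):
        # gene detected in 4 of 6 cells is dropped at the 5-cell floor
        dense = np.full((3, 6), 5)
        dense[2, :] = [1, 1, 1, 1, 0, 0]
        m = matrix_from_dense(dense)
        t = QCThresholds(umi_min=0, umi_max=10**6, genes_min=0, genes_max=10**6, min_cells_per_gene=5)
        out, report = filter_cells_genes(m, compute_cell_qc(m), t)
        assert out.gene_ids == ["g0", "g1"]
        assert report["n_genes_removed"] == 1

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            QCThresholds(umi_min=2000, umi_max=1000)
        with pytest.raises(ValueError):
            QCThresholds(mito_max=1.5)

    def test_idempotent_on_demo(self, demo_data, demo_processed):
        filtered, _, _, _ = demo_processed
        again, report2 = filter_cells_genes(filtered, compute_cell_qc(filtered))
        assert again.cell_ids == filtered.cell_ids
        assert again.gene_ids == filtered.gene_ids


class TestLogNormalize:
    def test_formula_and_zeros(self):
        m = matrix_from_dense([[10], [9990]])
        nm = log_normalize(m)
        # count 10 in a 10,000-total cell -> ln(1 + 1e4*10/1e4) = ln(11)
        assert nm.values[0, 0] == pytest.approx(np.log(11))
        assert (nm.values.toarray() == 0).sum() == (m.counts.toarray() == 0).sum()

    def test_proportional_cells_scale_invariance(self):
        m = matrix_from_dense([[10, 5], [9990, 4995]])
        nm = log_normalize(m)
        assert nm.values[0, 0] == pytest.approx(nm.values[0, 1])
        assert nm.values[0, 1] == pytest.approx(np.log(11))

    def test_bad_scale_factor(self):
        m = matrix_from_dense([[1]])
        with pytest.raises(ValueError, match="scale_factor"):
            log_normalize(m, scale_factor=0)

    def test_all_zero_cell_rejected(self):
        m = matrix_from_dense([[1, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            log_normalize(m)

    def test_rank_order_preserved_within_cell(self):
        rng = np.random.default_rng(5)
        dense = rng.integers(0, 30, size=(40, 10))
        dense[0, :] += 1  # avoid an all-zero cell
        m = matrix_from_dense(dense)
        nm = log_normalize(m)
        for j in range(10):
            c = dense[:, j]
            v = nm.values[:, j].toarray().ravel()
            order = np.argsort(c, kind="stable")
            assert np.all(np.diff(v[order]) >= -1e-12)


class TestVariableGenes:
    def test_identical_samples_share_top_list(self):
        rng = np.random.default_rng(8)
        dense = rng.integers(0, 20, size=(50, 40)) + 1
        m = matrix_from_dense(np.hstack([dense, dense]))
        labels = ["s1"] * 40 + ["s2"] * 40
        nm = log_normalize(m)
        out = select_variable_genes(nm, labels, top_n=10)
        assert len(out) == 10
        assert (out["n_samples"] == 2).all()

    def test_disjoint_top_lists_union(self):
        # sample 1 is bimodal in g0, sample 2 in g1 -> union of top-1 lists has 2 genes
        base = np.full((3, 20), 5)
        s1 = base.copy()
        s1[0, ::2] = 50
        s2 = base.copy()
        s2[1, ::2] = 50
        m = matrix_from_dense(np.hstack([s1, s2]))
        nm = log_normalize(m)
        out = select_variable_genes(nm, ["s1"] * 20 + ["s2"] * 20, top_n=1)
        assert set(out["gene"]) == {"g0", "g1"}

    def test_top_n_exceeding_genes_warns(self):
        m = matrix_from_dense(np.full((4, 10), 3))
        nm = log_normalize(m)
        with pytest.warns(UserWarning, match="returning all"):
            out = select_variable_genes(nm, None, top_n=100)
        assert len(out) == 4

    def test_planted_bimodal_marker_in_top_decile(self, demo_processed):
        # marker genes are on in one population and nearly off elsewhere:
        # strongly overdispersed, so they should rank among the most
        # variable genes of the pooled sample
        _, _, nm, _ = demo_processed
        out = select_variable_genes(nm, None, top_n=max(1, nm.n_genes // 10))
        assert "PC0.marker1" in set(out["gene"])
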