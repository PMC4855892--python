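import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import toy_ct
from mepscope.stats import (
    _stars,
    detection_fraction,
    edges_to_graph,
    ks_fdr_table,
    mean_fold_change,
    spearman_network,
)


def bruteforce_ks(x, y):
    """sup |F1 - F2| over the pooled sample points."""
    pts = np.concatenate([x, y])
    f1 = np.array([(x <= t).mean() for t in pts])
    f2 = np.array([(y <= t).mean() for t in pts])
    return np.max(np.abs(f1 - f2))


def bh_stepup(p):
    """Independent Benjamini-Hochberg oracle: q_i = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestKsFdr:
    def test_identical_groups_null(self, expr, assignment):
        table = ks_fdr_table(expr, assignment, pairs=[("E-MEP", "E-MEP")])
        assert (table["ks_D"] == 0).all()
        assert (table["stars"] == "NS").all()

    def test_disjoint_supports_give_unit_D(self):
        from scipy.stats import ks_2samp

        assert ks_2samp([1, 2, 3], [4, 5, 6]).statistic == 1.0

    def test_program_genes_strongly_significant(self, expr, assignment):
        table = ks_fdr_table(expr, assignment)
        klf1 = table[(table.gene == "KLF1") & (table.pop_a == "Pre-MEP")
                     & (table.pop_b == "E-MEP")]
        assert (klf1["stars"] == "***").all()
        hk = table[table.gene.isin(["B2M", "GAPDH"])]
        assert (hk["ks_D"] < 0.3).all()

    def test_bh_hand_example(self):
        q = bh_stepup([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=50),
    )
    def test_bh_matches_statsmodels_route(self, p):
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_stepup(p))

    def test_star_thresholds_strict(self):
        assert _stars(0.05) == "NS"
        assert _stars(0.049999) == "*"
        assert _stars(0.0099) == "**"
        assert _stars(0.0009) == "***"

    def test_empty_population_rejected(self, expr, assignment):
        with pytest.raises(ValueError, match="Ghost"):
            ks_fdr_table(expr, assignment, pairs=[("E-MEP", "Ghost")])


class TestDetectionFraction:
    def test_arithmetic(self, assignment):
        labels = assignment.labels
        cells = list(labels.index[:4])
        ct = toy_ct(
            [[11, 13, 20], [11, 13, 40], [11, 13, 21], [11, 13, 40]],
            assays=["B2M", "GAPDH", "G"],
        )
        ct.ct.index = pd.Index(cells)
        ct.dropout.index = pd.Index(cells)
        ct.cell_meta.index = pd.Index(cells)
        frac = detection_fraction(ct, assignment, "G")
        assert frac["overall"] == 0.5

    def test_all_dropout_zero(self, qc_passed, assignment):
        ct = qc_passed
        gene = ct.assay_ids[2]
        forced = ct.select_assays(ct.assay_ids)
        forced.ct[gene] = ct.lod
        forced.dropout[gene] = True
        frac = detection_fraction(forced, assignment, gene)
        assert (frac == 0).all()

    def test_unknown_gene(self, qc_passed, assignment):
        with pytest.raises(KeyError):
            detection_fraction(qc_passed, assignment, "NOT_A_GENE")


class TestFoldChange:
    def test_equal_means_unity(self, expr, assignment):
        # housekeeping delta-Ct is ~identical across populations
        fold = mean_fold_change(expr, assignment, "B2M", "E-MEP")
        assert fold == pytest.approx(1.0, abs=0.1)

    def test_known_difference(self, assignment):
        labels = assignment.labels
        target = labels == "E-MEP"
        vals = np.where(target, -np.log2(5.0), 0.0)
        expr_df = pd.DataFrame({"G": vals, "H": 1.0}, index=labels.index)
        from mepscope.qc import ExpressionMatrix

        expr = ExpressionMatrix(
            norm_ct=expr_df,
            housekeeping_mean=pd.Series(13.0, index=labels.index),
            dropout=pd.DataFrame(False, index=labels.index, columns=["G", "H"]),
        )
        assert mean_fold_change(expr, assignment, "G", "E-MEP") == pytest.approx(5.0)

    def test_swap_gives_reciprocal(self, expr, assignment):
        f = mean_fold_change(expr, assignment, "KLF1", "E-MEP")
        counts = assignment.counts()
        # reciprocal symmetry holds for a two-population comparison
        two_pop = assignment.labels[assignment.labels != "MK-MEP"]
        from mepscope.discovery import PopulationAssignment

        sub = PopulationAssignment(
            labels=two_pop,
            cluster_index=assignment.cluster_index.loc[two_pop.index],
            evidence=assignment.evidence,
            seed=assignment.seed,
        )
        sub_expr = expr.select_genes(expr.gene_symbols)
        sub_expr = type(expr)(
            norm_ct=expr.norm_ct.loc[two_pop.index],
            housekeeping_mean=expr.housekeeping_mean.loc[two_pop.index],
            dropout=expr.dropout.loc[two_pop.index],
        )
        a = mean_fold_change(sub_expr, sub, "KLF1", "E-MEP")
        b = mean_fold_change(sub_expr, sub, "KLF1", "Pre-MEP")
        assert a * b == pytest.approx(1.0)
        assert f > 1.0  # KLF1 higher in the erythroid-primed population


class TestSpearmanNetwork:
    def test_monotone_transforms(self, expr, assignment):
        cells = expr.cell_ids[:50]
        df = pd.DataFrame(
            {
                "A": np.arange(50, dtype=float),
                "B": np.exp(np.arange(50) / 10.0),
                "C": -np.arange(50, dtype=float) ** 3,
            },
            index=cells,
        )
        from mepscope.qc import ExpressionMatrix

        e = ExpressionMatrix(
            norm_ct=-df,  # network correlates -dCt
            housekeeping_mean=pd.Series(0.0, index=cells),
            dropout=pd.DataFrame(False, index=cells, columns=df.columns),
        )
        edges, skipped = spearman_network(e, ["A", "B", "C"], min_abs_rho=0.0)
        rho = edges.set_index(["gene_a", "gene_b"])["spearman_rho"]
        assert rho[("A", "B")] == pytest.approx(1.0)
        assert rho[("A", "C")] == pytest.approx(-1.0)
        assert not skipped

    def test_hand_computed_rho(self):
        # ranks differ by d = (1, 1, 1, 1, 0): rho = 1 - 6*4/(5*24) = 0.8
        from scipy.stats import spearmanr

        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        assert spearmanr(x, y).statistic == pytest.approx(0.8)
        cells = [f"c{i}" for i in range(5)]
        from mepscope.qc import ExpressionMatrix

        e = ExpressionMatrix(
            norm_ct=pd.DataFrame({"X": [-v for v in x], "Y": [-v for v in y]}, index=cells),
            housekeeping_mean=pd.Series(0.0, index=cells),
            dropout=pd.DataFrame(False, index=cells, columns=["X", "Y"]),
        )
        edges, _ = spearman_network(e, ["X", "Y"], min_abs_rho=0.0)
        assert edges["spearman_rho"].iloc[0] == pytest.approx(0.8)

    def test_constant_gene_pairs_skipped(self, expr):
        cells = expr.cell_ids[:10]
        from mepscope.qc import ExpressionMatrix

        e = ExpressionMatrix(
            norm_ct=pd.DataFrame(
                {"A": np.arange(10.0), "K": 5.0, "B": np.arange(10.0)[::-1]},
                index=cells,
            ),
            housekeeping_mean=pd.Series(0.0, index=cells),
            dropout=pd.DataFrame(False, index=cells, columns=["A", "K", "B"]),
        )
        edges, skipped = spearman_network(e, ["A", "K", "B"], min_abs_rho=0.0)
        assert ("A", "K") in skipped and ("K", "B") in skipped
        assert set(zip(edges.gene_a, edges.gene_b)) == {("A", "B")}

    def test_symmetric_unit_diagonal(self, expr):
        from scipy.stats import spearmanr

        genes = ["KLF1", "VWF", "GATA1", "CD44"]
        rho = spearmanr(-expr.norm_ct[genes].to_numpy()).statistic
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)

    def test_graph_export(self, expr, assignment):
        cells = assignment.labels.index[assignment.labels == "E-MEP"]
        edges, _ = spearman_network(expr, ["KLF1", "TMOD1", "ANK1"], cells, 0.0)
        g = edges_to_graph(edges)
        assert g.number_of_edges() == len(edges)
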