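"""Co-dependency index exactness, baselines and descriptive metrics."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from scannotate.cdi import (
    cdi_test,
    de_descriptive_metrics,
    find_cdi_gene_gene,
    find_cdi_markers,
    find_conserved_cdi_markers,
    gini_index,
    wilcoxon_auc_markers,
    _bh_fdr,
)
from scannotate.io import Clustering, CountMatrix, log_normalize


def binom_tail_oracle(I: int, N: int, pi: float) -> float:
    """Brute-force inclusive upper binomial tail via exact combinatorics."""
    return sum(
        math.comb(N, x) * pi**x * (1 - pi) ** (N - x) for x in range(I, N + 1)
    )


class TestCdiTest:
    def test_perfect_marker_example(self):
        # gene expressed in exactly the 4 cells of a 4-cell cluster, N=10
        member = np.zeros(10, bool)
        member[:4] = True
        r = cdi_test(member.copy(), member)
        assert r.pi_gk == pytest.approx(0.16)
        assert r.coincidence == 4
        assert r.p == pytest.approx(binom_tail_oracle(4, 10, 0.16), rel=1e-9)
        assert r.ncdi == pytest.approx(1.0)

    def test_no_coincidence_gives_zero_cdi(self):
        expr = np.array([1, 1, 0, 0, 0], bool)
        member = np.array([0, 0, 1, 1, 1], bool)
        r = cdi_test(expr, member)
        assert r.p == 1.0 and r.cdi == 0.0 and r.ncdi == 0.0

    def test_matches_oracle_on_exhaustive_small_grid(self):
        rng = np.random.default_rng(0)
        for N in (1, 2, 5, 12, 20):
            member = rng.random(N) < 0.5
            if not member.any():
                member[0] = True
            for frac in (0.0, 0.3, 1.0):
                expr = rng.random(N) < frac
                r = cdi_test(expr, member)
                expect = binom_tail_oracle(r.coincidence, N, r.pi_gk)
                assert r.p == pytest.approx(expect, rel=1e-9, abs=1e-300)

    def test_log_space_survives_extreme_tails(self):
        # 2000 cells, perfectly coincident sparse marker: p underflows linear
        # space but the log-space tail stays finite and capped
        member = np.zeros(200_000, bool)
        member[:40_000] = True
        r = cdi_test(member.copy(), member)
        assert 0 < r.cdi <= 1e4
        assert np.isfinite(r.log10_p)

    def test_errors(self):
        with pytest.raises(ValueError):
            cdi_test(np.array([], bool), np.array([], bool))
        with pytest.raises(ValueError):
            cdi_test(np.ones(4, bool), np.zeros(4, bool))


class TestFindMarkers:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(8)
        counts = (rng.random((5, 12)) < 0.4).astype(int) * rng.integers(1, 5, (5, 12))
        counts[0, :6] = 3  # strong cluster-A marker
        counts[0, 6:] = 0
        m = CountMatrix([f"g{i}" for i in range(5)], [f"c{i}" for i in range(12)], sp.csr_matrix(counts))
        c = Clustering(resolution=0.5, labels=np.array(["A"] * 6 + ["B"] * 6))
        return m, c

    def test_composition_equals_per_pair_tests(self, toy):
        m, c = toy
        table = find_cdi_markers(m, c)
        expr = m.expressed().toarray().astype(bool)
        for rec in table.itertuples(index=False):
            single = cdi_test(expr[m.genes.index(rec.gene)], c.members(rec.cluster))
            assert rec.p == pytest.approx(single.p, rel=1e-12)
            assert rec.ncdi == pytest.approx(single.ncdi, rel=1e-12)

    def test_bdeg_attains_max_ncdi_in_its_group(self, two_group):
        m, meta, truth = two_group
        c = Clustering(resolution=0.0, labels=meta["group"].to_numpy())
        table = find_cdi_markers(m, c)
        bdegs = truth.genes_with("bDEG")
        # bDEGs are Group2-exclusive: their Group2 nCDI dominates their Group1 nCDI
        wide = table.pivot(index="gene", columns="cluster", values="ncdi")
        sub = wide.loc[[g for g in bdegs if wide.loc[g].max() > 0]]
        assert (sub["Group2"] >= sub["Group1"]).all()

    def test_constant_gene_symmetric_and_nonsignificant(self):
        counts = np.ones((2, 10), dtype=int)
        counts[1] = [1, 0] * 5
        m = CountMatrix(["const", "other"], [f"c{i}" for i in range(10)], sp.csr_matrix(counts))
        c = Clustering(resolution=0.0, labels=np.array(["A"] * 5 + ["B"] * 5))
        table = find_cdi_markers(m, c)
        const = table[table.gene == "const"]
        assert const["ncdi"].nunique() == 1
        assert (const["fdr"] > 0.5).all()

    def test_cluster_with_no_cells_rejected(self, toy):
        m, _ = toy
        with pytest.raises(ValueError):
            find_cdi_markers(m, Clustering(resolution=0, labels=np.array(["A"] * 12)))

    def test_pct_in_out_ranges(self, toy):
        m, c = toy
        table = find_cdi_markers(m, c)
        assert table["pct_in"].between(0, 100).all()
        assert table["pct_out"].between(0, 100).all()


class TestGeneGene:
    def test_self_co_dependence_is_one(self, two_group):
        m, _, _ = two_group
        expressed = np.asarray(m.expressed().sum(axis=1)).ravel()
        # moderately expressed gene (all-cell expression makes the perfect-
        # co-dependence reference degenerate: p = 1 for any gene)
        gene = m.genes[int(np.argmin(np.abs(expressed - m.n_cells // 4)))]
        table = find_cdi_gene_gene(m, [gene], [gene])
        assert table["ncdi"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_genes_zero_cdi(self):
        counts = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        m = CountMatrix(["a", "b"], list("wxyz"), sp.csr_matrix(counts))
        table = find_cdi_gene_gene(m, ["a"], ["b"])
        assert table["cdi"].iloc[0] == 0.0


class TestConserved:
    def test_fisher_combination_worked_example(self):
        # two groups with identical p = 0.05: chi2 = -2*2*ln(0.05) = 11.98,
        # df = 4, combined p ~ 0.0175 (closed-form chi-square tail for df=4:
        # exp(-x/2) * (1 + x/2))
        chi2 = -2 * 2 * math.log(0.05)
        oracle = math.exp(-chi2 / 2) * (1 + chi2 / 2)
        assert oracle == pytest.approx(0.01747, abs=2e-5)

        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, (6, 40))
        m = CountMatrix([f"g{i}" for i in range(6)], [f"c{i}" for i in range(40)], sp.csr_matrix(counts))
        c = Clustering(resolution=0, labels=np.array(["A", "B"] * 20))
        groups = np.array((["r1"] * 20) + (["r2"] * 20))
        table = find_conserved_cdi_markers(m, c, groups)
        per_group = [
            find_cdi_markers(
                CountMatrix(m.genes, [m.cells[i] for i in np.where(groups == g)[0]],
                            m.counts[:, groups == g]),
                Clustering(resolution=0, labels=c.labels[groups == g]),
            )
            for g in ("r1", "r2")
        ]
        row = table[(table.gene == "g0") & (table.cluster == "A")].iloc[0]
        lp = sum(
            t[(t.gene == "g0") & (t.cluster == "A")]["log10_p"].iloc[0] * math.log(10)
            for t in per_group
        )
        chi2 = -2 * lp
        assert row["statistic"] == pytest.approx(chi2, rel=1e-9)
        assert row["p"] == pytest.approx(math.exp(-chi2 / 2) * (1 + chi2 / 2), rel=1e-9)

    def test_single_group_equals_group_p(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 3, (5, 30))
        m = CountMatrix([f"g{i}" for i in range(5)], [f"c{i}" for i in range(30)], sp.csr_matrix(counts))
        c = Clustering(resolution=0, labels=np.array(["A", "B", "C"] * 10))
        combined = find_conserved_cdi_markers(m, c, np.array(["only"] * 30))
        single = find_cdi_markers(m, c)
        merged = combined.merge(single, on=["gene", "cluster"], suffixes=("_f", "_s"))
        # Fisher with one group: chi2 = -2 ln p on 2 df, which inverts to p
        np.testing.assert_allclose(merged["p_f"], merged["p_s"], rtol=1e-9)


class TestWilcoxon:
    def test_exact_counts_on_toy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 1.0, 8)
        b = rng.normal(0.0, 1.0, 8)
        vals = np.concatenate([a, b])
        counts = np.zeros((2, 16), dtype=int)
        counts[1] = 1  # keep second gene flat
        m = CountMatrix(["g", "flat"], [f"c{i}" for i in range(16)], sp.csr_matrix(counts))
        m.lognorm = sp.csr_matrix(np.vstack([vals, np.ones(16)]))
        c = Clustering(resolution=0, labels=np.array(["A"] * 8 + ["B"] * 8))
        table = wilcoxon_auc_markers(m, c)
        row = table[(table.gene == "g") & (table.cluster == "A")].iloc[0]
        # brute-force U statistic: count of (a_i > b_j) pairs (+0.5 per tie)
        u = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert row["statistic"] == pytest.approx(u)
        assert row["auroc"] == pytest.approx(u / 64)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert row["p"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_perfectly_separated_gene_has_auroc_one(self):
        lognorm = np.array([[2.0, 2.5, 3.0, 0.0, 0.0, 0.0]])
        m = CountMatrix(["g"], list("abcdef"), sp.csr_matrix((lognorm > 0).astype(int)))
        m.lognorm = sp.csr_matrix(lognorm)
        c = Clustering(resolution=0, labels=np.array(["in"] * 3 + ["out"] * 3))
        row = wilcoxon_auc_markers(m, c).query("cluster == 'in'").iloc[0]
        assert row["auroc"] == 1.0
        assert not row["excluded"]

    def test_identical_distribution_auroc_half(self):
        lognorm = np.ones((1, 10))
        m = CountMatrix(["g"], [f"c{i}" for i in range(10)], sp.csr_matrix(np.ones((1, 10), int)))
        m.lognorm = sp.csr_matrix(lognorm)
        c = Clustering(resolution=0, labels=np.array(["A"] * 5 + ["B"] * 5))
        row = wilcoxon_auc_markers(m, c).iloc[0]
        assert row["auroc"] == 0.5
        assert row["p"] == pytest.approx(1.0)

    def test_negative_lfc_flagged_excluded(self, two_group):
        m, meta, _ = two_group
        m = log_normalize(m)
        c = Clustering(resolution=0, labels=meta["group"].to_numpy())
        table = wilcoxon_auc_markers(m, c)
        assert (table["excluded"] == (table["log_fold_change"] <= 0)).all()


class TestNullCalibration:
    def test_independent_sparse_features_give_uniform_midp(self):
        # sparse regime (the method's domain): plug-in binomial tail is well
        # calibrated; mid-p adjusts for discreteness
        rng = np.random.default_rng(11)
        N = 500
        midps = []
        for _ in range(1000):
            expr = rng.random(N) < 0.1
            mem = rng.random(N) < 0.1
            if not mem.any():
                continue
            r = cdi_test(expr, mem)
            midps.append(r.p - 0.5 * stats.binom.pmf(r.coincidence, N, r.pi_gk))
        assert stats.kstest(midps, "uniform").pvalue > 0.01


class TestDescriptiveMetrics:
    def make(self, p_in, p_out):
        df = pd.DataFrame({"gene": ["g"], "cluster": ["A"], "pct_in": [p_in], "pct_out": [p_out]})
        counts = np.array([[3, 3, 0, 0], [1, 1, 1, 1]])
        m = CountMatrix(["g", "bg"], list("abcd"), sp.csr_matrix(counts))
        m = log_normalize(m)
        c = Clustering(resolution=0, labels=np.array(["A", "A", "B", "B"]))
        return de_descriptive_metrics(df, m, c)

    def test_symmetric_case(self):
        row = self.make(90.0, 10.0).iloc[0]
        assert row["sensitivity"] == pytest.approx(0.90)
        assert row["specificity"] == pytest.approx(0.90)
        assert row["ppv"] == pytest.approx(0.90)
        assert row["npv"] == pytest.approx(0.90)

    def test_perfect_marker(self):
        row = self.make(100.0, 0.0).iloc[0]
        assert all(row[k] == pytest.approx(1.0) for k in ("sensitivity", "specificity", "ppv", "npv"))

    def test_undefined_ppv_reported_missing(self):
        row = self.make(0.0, 0.0).iloc[0]
        assert np.isnan(row["ppv"])

    def test_gini_exclusive_gene_is_one(self):
        assert gini_index(np.array([1.0, 0, 0, 0])) == pytest.approx(1.0)

    def test_gini_uniform_gene_is_zero(self):
        assert gini_index(np.array([2.0, 2.0, 2.0])) == pytest.approx(0.0)

    def test_printed_form_unbounded_retained_for_audit(self):
        x = np.array([5.0, 0.0, 0.0])
        assert gini_index(x, printed=True) > 1  # the as-printed algebra


class TestBH:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(200) ** 2
        fdr = _bh_fdr(p)
        assert (fdr >= p - 1e-12).all() and (fdr <= 1).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
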