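"""One-sided deviance enrichment tests against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats

import statsmodels.api as sm

from cnvpathways.enrichment import (
    DevianceTester,
    bonferroni_threshold,
    deviance_test,
    significant_genes_in_pathway,
    test_all_pathways as run_all_pathways,
    test_single_genes as run_single_genes,
    EnrichmentResult,
)
from cnvpathways.hits import build_hit_index
from cnvpathways.types import DesignRow, GeneInterval, PathwayDB


def rows_for_table(case_hits, case_n, ctrl_hits, ctrl_n, length=600_000, outside=5):
    """Covariate-free design realizing a 2x2 hits table."""
    rows = []
    k = 0
    for label, n, hits in ((1, case_n, case_hits), (0, ctrl_n, ctrl_hits)):
        for i in range(n):
            rows.append(
                DesignRow(f"A:{k:03d}", label, length, outside, 1 if i < hits else 0, "A")
            )
            k += 1
    return rows


def two_binomial_lrt(a, m, b, n):
    """Oracle: likelihood-ratio statistic of a 2x2 table by direct
    maximization of the two binomial likelihoods (closed form at the MLE)."""

    def ll(h, t):
        if t == 0 or h == 0 or h == t:
            out = 0.0
            if 0 < h < t:
                raise AssertionError
            if t and 0 < h:
                out = h * math.log(h / t)
            if t and h < t:
                out += (t - h) * math.log(1 - h / t)
            return out
        p = h / t
        return h * math.log(p) + (t - h) * math.log(1 - p)

    full = ll(a, m) + ll(b, n)
    null = ll(a + b, m + n)
    return 2.0 * (full - null)


class TestTwoByTwoOracle:
    def test_frozen_example_four_vs_one_hits(self):
        # 12 CNVs (6 case / 6 control), hits 4 case vs 1 control; expected
        # values computed with the two-binomial oracle above
        res = deviance_test(rows_for_table(4, 6, 1, 6))
        assert res.deviance_drop == pytest.approx(3.2557338578632056, abs=1e-8)
        assert res.p_one_sided == pytest.approx(0.035587035585177236, abs=1e-8)
        assert res.coefficient > 0

    def test_exhaustive_small_margins(self):
        # all tables with both group sizes <= 12 and a non-constant hit column
        for m in range(2, 13):
            for n in range(2, 13):
                for a in range(0, m + 1):
                    for b in range(0, n + 1):
                        if a + b == 0 or a + b == m + n:
                            continue  # degenerate: hit column constant
                        res = deviance_test(rows_for_table(a, m, b, n))
                        if res.method == "penalized":
                            continue  # separated corners leave MLE territory
                        g = two_binomial_lrt(a, m, b, n)
                        assert res.deviance_drop == pytest.approx(g, abs=1e-8), (a, m, b, n)

    def test_one_sidedness_depletion_gives_large_p(self):
        res = deviance_test(rows_for_table(1, 6, 4, 6))
        assert res.coefficient < 0
        assert res.p_one_sided > 0.5

    def test_label_swap_reflects_p(self):
        rows = rows_for_table(4, 7, 2, 9)
        res = deviance_test(rows)
        swapped = [
            DesignRow(r.cnv_id, 1 - r.label, r.cnv_length, r.genes_outside, r.pathway_hit, r.cohort)
            for r in rows
        ]
        res_swapped = deviance_test(swapped)
        assert res_swapped.coefficient == pytest.approx(-res.coefficient, abs=1e-6)
        assert res_swapped.p_one_sided == pytest.approx(1.0 - res.p_one_sided, abs=1e-8)


class TestAgainstStatsmodels:
    def test_deviance_and_coefficient_match_glm(self):
        rng = np.random.default_rng(3)
        n = 150
        length_kb = rng.normal(700, 150, n)
        outside = rng.poisson(6, n).astype(float)
        hit = rng.binomial(1, 0.25, n).astype(float)
        y = rng.binomial(1, 0.45, n).astype(float)
        tester = DevianceTester(length_kb, outside, hit)
        coef, dev, p, conv, method, _ = tester.test(y)
        assert method == "mle" and conv
        Xf = np.column_stack([np.ones(n), length_kb, outside, hit])
        mf = sm.GLM(y, Xf, family=sm.families.Binomial()).fit()
        m0 = sm.GLM(y, Xf[:, :3], family=sm.families.Binomial()).fit()
        assert dev == pytest.approx(m0.deviance - mf.deviance, abs=1e-6)
        assert coef == pytest.approx(mf.params[3], abs=1e-6)
        tail = stats.chi2.sf(dev, 1)
        expected_p = 0.5 * tail if coef > 0 else 1 - 0.5 * tail
        assert p == pytest.approx(expected_p, abs=1e-12)


class TestNumericalProperties:
    def test_deviance_invariant_to_length_rescaling(self):
        rng = np.random.default_rng(8)
        n = 80
        length = rng.uniform(500, 3000, n)
        outside = rng.poisson(4, n).astype(float)
        hit = rng.binomial(1, 0.3, n).astype(float)
        y = rng.binomial(1, 0.5, n).astype(float)
        d1 = DevianceTester(length, outside, hit).test(y)[1]
        d2 = DevianceTester(length * 1000.0, outside, hit).test(y)[1]
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_separation_triggers_penalized_refit(self):
        # hit column perfectly predicts case status -> infinite MLE
        rows = []
        for i in range(12):
            rows.append(DesignRow(f"A:{i:02d}", 1, 600_000 + 1_000 * i, 3, 1, "A"))
        for i in range(12, 24):
            rows.append(DesignRow(f"A:{i:02d}", 0, 590_000 + 1_000 * i, 3, 0, "A"))
        res = deviance_test(rows)
        assert res.method == "penalized"
        assert res.coefficient > 0
        assert res.p_one_sided < 0.05

    def test_constant_hit_column_degenerate(self):
        rows = rows_for_table(0, 5, 0, 5)
        res = deviance_test(rows)
        assert res.method == "degenerate"
        assert res.p_one_sided == 1.0
        assert res.deviance_drop == 0.0

    def test_requires_both_labels(self):
        rows = [DesignRow("A:0", 1, 600_000, 1, 0, "A")]
        with pytest.raises(ValueError):
            deviance_test(rows)


class TestSweepAndGeneTests:
    def test_empty_db_gives_empty_results(self, tiny_study):
        genes, _, cnvs = tiny_study
        index = build_hit_index(cnvs, genes)
        assert run_all_pathways(cnvs, index, PathwayDB()) == []

    def test_results_ordered_by_pathway_id(self, tiny_study):
        genes, db, cnvs = tiny_study
        index = build_hit_index(cnvs, genes)
        results = run_all_pathways(cnvs, index, db)
        ids = [r.pathway_id for r in results]
        assert ids == sorted(ids)

    def test_singleton_pathway_equals_gene_test(self, tiny_study):
        genes, _, cnvs = tiny_study
        index = build_hit_index(cnvs, genes)
        gene = sorted(genes)[0]
        db = PathwayDB()
        db.add(gene.gene_id, {gene.gene_id})
        (via_pathway,) = run_all_pathways(cnvs, index, db)
        via_gene = [
            r for r in run_single_genes(cnvs, index, [gene]) if r.pathway_id == gene.gene_id
        ][0]
        assert via_pathway == via_gene

    def test_unhit_gene_is_degenerate(self, tiny_study):
        genes, _, cnvs = tiny_study
        index = build_hit_index(cnvs, genes)
        unhit = [g for g in genes if not index.cnvs_hitting(g.gene_id)]
        assert unhit, "expected at least one unhit gene in the tiny study"
        (res,) = run_single_genes(cnvs, index, unhit[:1])
        assert res.method == "degenerate" and res.p_one_sided == 1.0


class TestBonferroni:
    def test_paper_scale_threshold(self):
        assert bonferroni_threshold(0.05, 10_240) == pytest.approx(4.8828125e-6)

    @pytest.mark.parametrize("n,expected", [(1, 0.05), (2, 0.025)])
    def test_small_counts(self, n, expected):
        assert bonferroni_threshold(0.05, n) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, 10)


class TestSignificantGenes:
    @staticmethod
    def gene_result(gene, p):
        return EnrichmentResult(gene, 1, 0, 1.0, 1.0, p, True, "mle")

    def test_selects_below_alpha_sorted_by_p(self):
        results = [self.gene_result("G1", 0.03), self.gene_result("G2", 0.2)]
        assert significant_genes_in_pathway({"G1", "G2"}, results, 0.05) == ["G1"]

    def test_none_below_alpha(self):
        results = [self.gene_result("G1", 0.5)]
        assert significant_genes_in_pathway({"G1"}, results, 0.05) == []

    def test_alpha_one_takes_all_members(self):
        results = [self.gene_result("G1", 0.9), self.gene_result("G2", 0.1), self.gene_result("X", 0.01)]
        assert significant_genes_in_pathway({"G1", "G2"}, results, 1.0) == ["G2", "G1"]
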