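"""Properties of the synthetic-data generator."""

import dataclasses

import numpy as np
import pytest

from cnvpathways.simulate import (
    SimulationScenario,
    scenario_presets,
    simulate_cnvs,
    simulate_genome,
    simulate_pathways,
    simulate_study,
)
from cnvpathways.types import Inheritance, Label


class TestGenome:
    def test_requested_gene_count_and_disjointness(self):
        sc = SimulationScenario(seed=1, n_chrom=1, chrom_length=100_000_000, n_genes=100)
        genes = sorted(simulate_genome(sc), key=lambda g: g.start)
        assert len(genes) == 100
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start  # disjoint and ordered

    def test_deterministic_under_seed(self):
        sc = SimulationScenario(seed=7)
        assert simulate_genome(sc) == simulate_genome(sc)

    def test_zero_genes(self):
        sc = SimulationScenario(seed=1, n_genes=0)
        assert simulate_genome(sc) == set()

    def test_infeasible_density_raises(self):
        sc = SimulationScenario(seed=1, n_chrom=1, chrom_length=1_000_000, n_genes=500)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_genome(sc)

    def test_gene_clusters_tighten_spacing(self):
        base = dict(seed=3, n_chrom=1, chrom_length=75_000_000, n_genes=1000)
        uniform = sorted(
            simulate_genome(SimulationScenario(**base)), key=lambda g: g.start
        )
        clumped = sorted(
            simulate_genome(
                SimulationScenario(**base, gene_cluster_fraction=0.8, gene_cluster_size=25)
            ),
            key=lambda g: g.start,
        )
        gaps = lambda gs: np.array([b.start - a.end for a, b in zip(gs, gs[1:])])
        assert np.median(gaps(clumped)) < np.median(gaps(uniform))


class TestPathways:
    def test_fully_clustered_pathways_span_one_window(self, tiny_scenario):
        sc = dataclasses.replace(
            tiny_scenario, clustered_fraction=1.0, pathway_size_range=(5, 5),
            cluster_window_genes=5, n_pathways=20,
        )
        genes = simulate_genome(sc)
        ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
        pos = {g.gene_id: i for i, g in enumerate(ordered)}
        db = simulate_pathways(sc, genes)
        for pid in db:
            idxs = sorted(pos[g] for g in db.genes(pid))
            assert idxs[-1] - idxs[0] < 5  # contiguous in genomic order
            assert len({ordered[i].chrom for i in idxs}) == 1

    def test_random_pathways_span_like_random_sets(self, tiny_scenario):
        # clustered pathways span far less of the genome than random ones
        sc = dataclasses.replace(tiny_scenario, clustered_fraction=0.5)
        genes = simulate_genome(sc)
        db = simulate_pathways(sc, genes)
        by_id = {g.gene_id: g for g in genes}

        def span(pid):
            members = [by_id[g] for g in db.genes(pid)]
            chroms = {g.chrom for g in members}
            if len(chroms) > 1:
                return np.inf
            return max(g.end for g in members) - min(g.start for g in members)

        clustered = [span(p) for p in db if db.descriptions[p] == "clustered"]
        random_ = [span(p) for p in db if db.descriptions[p] == "random"]
        assert np.median(clustered) < np.median([s for s in random_ if np.isfinite(s)] or [np.inf])
        assert sum(np.isinf(s) for s in random_) > len(random_) / 2

    def test_fixed_size_range(self, tiny_scenario):
        sc = dataclasses.replace(tiny_scenario, pathway_size_range=(3, 3))
        genes = simulate_genome(sc)
        db = simulate_pathways(sc, genes)
        assert all(len(db.genes(p)) == 3 for p in db)

    def test_oversized_pathway_rejected(self, tiny_scenario):
        sc = dataclasses.replace(tiny_scenario, n_genes=5, pathway_size_range=(10, 10))
        genes = simulate_genome(sc)
        with pytest.raises(ValueError):
            simulate_pathways(sc, genes)


class TestCnvs:
    def test_bit_identical_under_seed(self, tiny_scenario):
        g1, d1, c1 = simulate_study(tiny_scenario)
        g2, d2, c2 = simulate_study(tiny_scenario)
        assert g1 == g2 and d1.pathways == d2.pathways and c1 == c2

    def test_all_lengths_truncated_above_minimum(self, tiny_study, tiny_scenario):
        _, _, cnvs = tiny_study
        assert all(c.length > tiny_scenario.cnv_min_length for c in cnvs)

    def test_cohort_and_label_counts(self, tiny_study, tiny_scenario):
        _, _, cnvs = tiny_study
        sc = tiny_scenario
        counts = {
            (co, la): sum(1 for c in cnvs if c.cohort == co and c.label is la)
            for co in "AB"
            for la in Label
        }
        assert counts[("A", Label.CASE)] == sc.n_case_a
        assert counts[("A", Label.CONTROL)] == sc.n_ctrl_a
        assert counts[("B", Label.CASE)] == sc.n_case_b
        assert counts[("B", Label.CONTROL)] == sc.n_ctrl_b

    def test_inheritance_only_on_b_cases(self, tiny_study):
        _, _, cnvs = tiny_study
        for c in cnvs:
            if c.cohort == "B" and c.label is Label.CASE:
                assert c.inheritance in (Inheritance.DE_NOVO, Inheritance.INHERITED)
            else:
                assert c.inheritance is Inheritance.UNKNOWN

    def test_planted_boost_raises_case_hit_rate(self, tiny_scenario):
        from cnvpathways.hits import build_hit_index

        sc = dataclasses.replace(tiny_scenario, planted_pathways=(("PW000", 8.0, 8.0),))
        genes, db, cnvs = simulate_study(sc)
        index = build_hit_index(cnvs, genes)
        pw = db.genes("PW000")
        case_hits = sum(
            1 for c in cnvs if c.label is Label.CASE and index.genes_hit(c.cnv_id) & pw
        )
        null_genes, null_db, null_cnvs = simulate_study(tiny_scenario)
        null_index = build_hit_index(null_cnvs, null_genes)
        null_pw = null_db.genes("PW000")
        null_case_hits = sum(
            1
            for c in null_cnvs
            if c.label is Label.CASE and null_index.genes_hit(c.cnv_id) & null_pw
        )
        assert case_hits > 2 * max(1, null_case_hits)

    def test_length_tilt_shifts_case_lengths(self, tiny_scenario):
        sc = dataclasses.replace(tiny_scenario, case_length_tilt=2.0)
        _, _, cnvs = simulate_study(sc)
        case_len = np.mean([c.length for c in cnvs if c.label is Label.CASE])
        ctrl_len = np.mean([c.length for c in cnvs if c.label is Label.CONTROL])
        assert case_len > ctrl_len


class TestPresets:
    def test_expected_names(self):
        assert set(scenario_presets()) == {
            "null",
            "planted_shared",
            "planted_disjoint",
            "clustered_null",
        }

    def test_null_has_no_signal(self):
        sc = scenario_presets()["null"]
        assert sc.planted_pathways == ()
        assert sc.shared_locus_rate == 0.0
        assert sc.case_length_tilt == 0.0

    def test_planted_shared_boosts_same_pathway_in_both(self):
        sc = scenario_presets()["planted_shared"]
        ((pid, ba, bb),) = sc.planted_pathways
        assert ba > 1 and bb > 1

    def test_planted_disjoint_separates_cohorts(self):
        sc = scenario_presets()["planted_disjoint"]
        boosts = {pid: (ba, bb) for pid, ba, bb in sc.planted_pathways}
        assert any(ba > 1 and bb == 1 for ba, bb in boosts.values())
        assert any(ba == 1 and bb > 1 for ba, bb in boosts.values())

    def test_clustered_null_is_confounded_but_unenriched(self):
        sc = scenario_presets()["clustered_null"]
        assert sc.clustered_fraction == 0.5
        assert sc.planted_pathways == ()
        assert sc.case_length_tilt > 0
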