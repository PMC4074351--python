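"""CNV- and pathway-level inclusion rules."""

import pytest

from cnvpathways.filters import (
    FilterConfig,
    cluster_by_reciprocal_overlap,
    exclude_region_cnvs,
    exclude_region_genes,
    filter_by_frequency,
    filter_by_length,
    filter_pathways,
    remove_cross_overlapping_case_cnvs,
    subset_by_type,
)
from cnvpathways.regions import builtin_exclusion_regions
from cnvpathways.types import CnvType, GeneInterval, PathwayDB

from conftest import make_cnv


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,kept", [(500_000, False), (500_001, True), (499_999, False)]
    )
    def test_strict_threshold(self, length, kept):
        cnv = make_cnv(start=1, end=length)
        assert (filter_by_length([cnv], 500_000) == [cnv]) is kept

    def test_empty_input(self):
        assert filter_by_length([], 500_000) == []

    def test_idempotent(self, tiny_study):
        _, _, cnvs = tiny_study
        once = filter_by_length(cnvs, 600_000)
        assert filter_by_length(once, 600_000) == once


class TestFrequencyFilter:
    def test_singleton_kept_in_large_sample(self):
        cnv = make_cnv()
        assert filter_by_frequency([cnv], total_samples=5_808) == [cnv]

    def test_common_cluster_removed(self):
        cnvs = [
            make_cnv(cnv_id=f"A:{i}", sample_id=f"S{i}") for i in range(60)
        ]  # 60 identical CNVs among 1,000 samples: freq 0.06 >= 0.01
        assert filter_by_frequency(cnvs, total_samples=1_000) == []

    def test_low_mutual_overlap_not_clustered(self):
        a = make_cnv(cnv_id="A:0", start=1_000_000, end=2_000_000)
        b = make_cnv(cnv_id="A:1", start=1_900_001, end=2_900_001)  # 10% RO
        clusters = cluster_by_reciprocal_overlap([a, b], ro=0.5)
        assert len(clusters) == 2

    def test_zero_total_samples_rejected(self):
        with pytest.raises(ValueError):
            filter_by_frequency([make_cnv()], total_samples=0)

    def test_idempotent(self):
        cnvs = [make_cnv(cnv_id=f"A:{i}", sample_id=f"S{i}") for i in range(5)]
        once = filter_by_frequency(cnvs, total_samples=300)
        assert filter_by_frequency(once, total_samples=300) == once


class TestPathwayFilter:
    @staticmethod
    def db_of(sizes):
        db = PathwayDB()
        for pid, n in sizes.items():
            db.add(pid, {f"{pid}_G{i}" for i in range(n)})
        return db

    def test_size_bounds_inclusive_and_hit_floor(self):
        db = self.db_of({"small": 2, "big": 1_500, "mid": 50})
        counts = {"small": 100, "big": 10, "mid": 9}
        kept = filter_pathways(db, FilterConfig(), counts)
        assert set(kept.pathways) == {"big"}  # 1,500 genes ok, 10 hits ok

    def test_unknown_pathway_in_counts_is_error(self):
        db = self.db_of({"a": 5})
        with pytest.raises(ValueError, match="ghost"):
            filter_pathways(db, FilterConfig(), {"a": 10, "ghost": 3})

    def test_idempotent(self):
        db = self.db_of({"a": 5, "b": 2, "c": 10})
        counts = {"a": 12, "b": 30, "c": 4}
        once = filter_pathways(db, FilterConfig(), counts)
        again = filter_pathways(once, FilterConfig(), {p: counts[p] for p in once})
        assert set(again.pathways) == set(once.pathways)


class TestRegionExclusion:
    def test_gene_inside_printed_chr16_region_removed(self):
        gene = GeneInterval("G", "chr16", 29_600_000, 29_700_000)
        assert exclude_region_genes({gene}, builtin_exclusion_regions()) == set()

    def test_gene_on_unlisted_chromosome_kept(self):
        gene = GeneInterval("G", "chr20", 1, 10_000_000)
        assert exclude_region_genes({gene}, builtin_exclusion_regions()) == {gene}

    def test_empty_region_list_is_identity(self):
        gene = GeneInterval("G", "chr16", 29_600_000, 29_700_000)
        assert exclude_region_genes({gene}, ()) == {gene}

    def test_cnv_variant_removes_whole_records(self):
        inside = make_cnv(chrom="chr16", start=29_000_000, end=29_560_000)
        outside = make_cnv(cnv_id="A:1", chrom="chr16", start=40_000_000, end=40_600_000)
        assert exclude_region_cnvs([inside, outside], builtin_exclusion_regions()) == [outside]


class TestCrossOverlapRemoval:
    def test_mutual_overlap_removes_both(self):
        a = [make_cnv(cnv_id="A:0", start=1, end=2_000_000)]
        b = [make_cnv(cnv_id="B:0", cohort="B", start=1_500_000, end=3_000_000)]
        assert remove_cross_overlapping_case_cnvs(a, b) == ([], [])

    def test_disjoint_chromosomes_identity(self):
        a = [make_cnv(cnv_id="A:0", chrom="chr1")]
        b = [make_cnv(cnv_id="B:0", cohort="B", chrom="chr2")]
        assert remove_cross_overlapping_case_cnvs(a, b) == (a, b)

    def test_removal_uses_original_opposite_list(self):
        # chain: a1 overlaps b1; b1 overlaps a1 only; a2 overlaps b2 ...
        a1 = make_cnv(cnv_id="A:0", start=1_000_000, end=2_000_000)
        b1 = make_cnv(cnv_id="B:0", cohort="B", start=1_500_000, end=2_500_000)
        a2 = make_cnv(cnv_id="A:1", start=2_400_000, end=3_400_000)
        out_a, out_b = remove_cross_overlapping_case_cnvs([a1, a2], [b1])
        # a2 overlaps b1 (original list) so it goes too, even though b1 itself is removed
        assert out_a == [] and out_b == []

    def test_symmetric_under_argument_swap(self, tiny_study):
        _, _, cnvs = tiny_study
        from cnvpathways.types import Label

        a = [c for c in cnvs if c.cohort == "A" and c.label is Label.CASE]
        b = [c for c in cnvs if c.cohort == "B" and c.label is Label.CASE]
        ab = remove_cross_overlapping_case_cnvs(a, b)
        ba = remove_cross_overlapping_case_cnvs(b, a)
        assert ab == (ba[1], ba[0])


class TestTypeSubset:
    def test_counts_by_type(self):
        cnvs = [
            make_cnv(cnv_id=f"A:{i}", cnv_type=CnvType.DELETION) for i in range(21)
        ] + [
            make_cnv(cnv_id=f"A:{21 + i}", cnv_type=CnvType.DUPLICATION)
            for i in range(64)
        ]
        assert len(subset_by_type(cnvs, CnvType.DELETION)) == 21
        assert len(subset_by_type(cnvs, CnvType.DUPLICATION)) == 64

    def test_no_matching_type_gives_empty(self):
        dels = [make_cnv(cnv_type=CnvType.DELETION)]
        assert subset_by_type(dels, CnvType.DUPLICATION) == []
        assert subset_by_type([], CnvType.DELETION) == []
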