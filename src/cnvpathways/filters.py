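"""CNV- and pathway-level inclusion rules.

The analysis is restricted to large (>500 kb, strict) rare (<1% carrier
frequency) CNVs, and to pathways of 3–1,500 genes (inclusive) with at least
10 CNV hits in the total sample. Secondary analyses additionally exclude
genes in known autism loci, remove case CNVs that physically overlap case
CNVs of the other cohort, or restrict to deletions/duplications alone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .types import CnvRecord, CnvType, GeneInterval, PathwayDB, RegionList


@dataclass(frozen=True)
class FilterConfig:
    min_cnv_length: int = 500_000  # strict ">"
    max_frequency: float = 0.01  # strict "<" to survive
    min_pathway_genes: int = 3
    max_pathway_genes: int = 1_500
    min_total_hits: int = 10
    reciprocal_overlap_for_frequency: float = 0.5

    def __post_init__(self) -> None:
        if min(
            self.min_cnv_length,
            self.max_frequency,
            self.min_pathway_genes,
            self.max_pathway_genes,
            self.min_total_hits,
            self.reciprocal_overlap_for_frequency,
        ) <= 0:
            raise ValueError("all filter thresholds must be positive")
        if self.min_pathway_genes > self.max_pathway_genes:
            raise ValueError("min_pathway_genes > max_pathway_genes")


def filter_by_length(
    cnvs: Sequence[CnvRecord], min_length: int = 500_000
) -> list[CnvRecord]:
    """Keep CNVs with length strictly greater than ``min_length``."""
    return [c for c in cnvs if c.length > min_length]


def _reciprocal_overlap(a: CnvRecord, b: CnvRecord) -> float:
    """min of mutual overlap fractions; 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def cluster_by_reciprocal_overlap(
    cnvs: Sequence[CnvRecord], ro: float = 0.5
) -> list[list[CnvRecord]]:
    """Single-linkage clusters of CNVs linked at reciprocal overlap >= ro."""
    parent = list(range(len(cnvs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, c in enumerate(cnvs):
        by_chrom[c.chrom].append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: cnvs[i].start)
        for pos, i in enumerate(idxs):
            for j in idxs[pos + 1 :]:
                if cnvs[j].start > cnvs[i].end:
                    break
                if _reciprocal_overlap(cnvs[i], cnvs[j]) >= ro:
                    union(i, j)
    clusters: dict[int, list[CnvRecord]] = defaultdict(list)
    for i, c in enumerate(cnvs):
        clusters[find(i)].append(c)
    return list(clusters.values())


def filter_by_frequency(
    cnvs: Sequence[CnvRecord],
    total_samples: int,
    max_freq: float = 0.01,
    ro: float = 0.5,
) -> list[CnvRecord]:
    """Remove CNV clusters whose carrier frequency reaches ``max_freq``.

    CNVs are single-linkage clustered at reciprocal overlap >= ``ro``; a
    cluster's carrier count is its number of distinct sample_ids, and the
    whole cluster is removed when carriers / total_samples >= max_freq.
    """
    if total_samples <= 0:
        raise ValueError("total_samples must be positive")
    keep_ids: set[str] = set()
    for cluster in cluster_by_reciprocal_overlap(cnvs, ro=ro):
        carriers = len({c.sample_id for c in cluster})
        if carriers / total_samples < max_freq:
            keep_ids.update(c.cnv_id for c in cluster)
    return [c for c in cnvs if c.cnv_id in keep_ids]


def filter_pathways(
    db: PathwayDB,
    config: FilterConfig,
    hit_counts: Mapping[str, int],
) -> PathwayDB:
    """Keep pathways with an in-range gene count and enough total hits.

    ``hit_counts`` must come from the combined case+control CNV set; small
    pathways and thinly hit ones are excluded to avoid apparent enrichment
    driven by a handful of CNVs. Hit counts must be recomputed after any
    gene or CNV removal (region exclusion, overlap removal, type subsets).
    """
    unknown = set(hit_counts) - set(db.pathways)
    if unknown:
        raise ValueError(f"hit_counts for pathways absent from db: {sorted(unknown)}")
    keep = [
        pid
        for pid in db
        if config.min_pathway_genes <= len(db.genes(pid)) <= config.max_pathway_genes
        and hit_counts.get(pid, 0) >= config.min_total_hits
    ]
    return db.subset(keep)


def exclude_region_genes(
    genes: set[GeneInterval], regions: RegionList
) -> set[GeneInterval]:
    """Drop genes whose span overlaps any exclusion region by >=1 bp."""
    kept = set()
    for g in genes:
        if not any(
            r.chrom == g.chrom and g.start <= r.end and g.end >= r.start
            for r in regions
        ):
            kept.add(g)
    return kept


def exclude_region_cnvs(
    cnvs: Sequence[CnvRecord], regions: RegionList
) -> list[CnvRecord]:
    """Drop whole CNVs touching any exclusion region (>=1 bp).

    Distinct from :func:`exclude_region_genes`: the physical-overlap test
    removes CNVs in the regions, the pathway reruns remove genes.
    """
    return [
        c
        for c in cnvs
        if not any(c.overlaps(r.chrom, r.start, r.end) for r in regions)
    ]


def remove_cross_overlapping_case_cnvs(
    cases_a: Sequence[CnvRecord], cases_b: Sequence[CnvRecord]
) -> tuple[list[CnvRecord], list[CnvRecord]]:
    """Symmetrically drop case CNVs overlapping (>=1 bp) any case CNV of the
    other cohort; each side is compared against the other's ORIGINAL list."""

    def survivors(
        xs: Sequence[CnvRecord], ys: Sequence[CnvRecord]
    ) -> list[CnvRecord]:
        by_chrom: dict[str, list[CnvRecord]] = defaultdict(list)
        for y in ys:
            by_chrom[y.chrom].append(y)
        return [
            x
            for x in xs
            if not any(
                x.start <= y.end and x.end >= y.start for y in by_chrom[x.chrom]
            )
        ]

    return survivors(cases_a, cases_b), survivors(cases_b, cases_a)


def subset_by_type(cnvs: Sequence[CnvRecord], cnv_type: CnvType) -> list[CnvRecord]:
    """Keep deletions or duplications only."""
    return [c for c in cnvs if c.cnv_type is cnv_type]
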