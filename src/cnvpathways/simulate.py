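"""Synthetic genomes, pathway databases and two-cohort CNV sets.

The generator emulates the statistical structure the analysis assumes:
large (>500 kb) rare CNVs with a right-skewed length spread, genes that can
be physically clustered inside some pathways, and two case/control cohorts
whose case CNVs may carry (a) a planted excess of hits on target pathways,
(b) a shared-locus tendency across cohorts, or (c) a pathway-agnostic
excess of gene hits. Default cohort CNV counts mirror a realistic two-study
design (85/78 and 133/215 CNVs above 500 kb); the genome is scaled down so
per-pathway hit counts land in the regime the >=10-hit pathway filter
targets.

Planted enrichment works by re-anchoring: a boosted case CNV is relocated
to overlap a random gene of the target pathway, which multiplies the
pathway hit rate while preserving the marginal CNV length and count — the
signal the enrichment test is built to detect, and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import (
    CnvRecord,
    CnvType,
    GeneInterval,
    Inheritance,
    Label,
    PathwayDB,
)


@dataclass(frozen=True)
class SimulationScenario:
    seed: int = 0
    n_chrom: int = 4
    chrom_length: int = 75_000_000
    n_genes: int = 4_000
    gene_length: int = 15_000  # mean; individual lengths uniform in [0.5, 1.5]x
    # fraction of genes laid down in tight genomic clusters (runs of
    # ~gene_cluster_size adjacent genes); 0 = uniform placement
    gene_cluster_fraction: float = 0.0
    gene_cluster_size: int = 20
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (20, 20)
    clustered_fraction: float = 0.0
    # a clustered pathway samples its genes from a contiguous stretch of
    # this many consecutive genes (>= pathway size); small values give
    # back-to-back genes, larger ones a loose neighbourhood
    cluster_window_genes: int = 100
    disjoint_pathways: bool = True
    n_case_a: int = 85
    n_ctrl_a: int = 78
    n_case_b: int = 133
    n_ctrl_b: int = 215
    cnv_length_median: int = 700_000
    cnv_length_sigma: float = 0.4
    cnv_min_length: int = 500_000
    # (pathway_id, relative case hit-rate boost in A, in B); boosts >= 1
    planted_pathways: tuple[tuple[str, float, float], ...] = ()
    shared_locus_rate: float = 0.0
    n_shared_loci: int = 10
    # pathway-agnostic case gene-load: prob. a case CNV is re-anchored onto
    # a random gene (any pathway) — a confounder, not pathway enrichment
    case_gene_anchor_rate: float = 0.0
    # exponential tilt (per Mb) on case CNV lengths relative to controls
    # (case CNVs tend to run larger): the case length density is
    # proportional to exp(tilt * length_Mb) times the control density, so
    # the case/control log-odds is exactly linear in CNV length — the
    # confound the regression's length covariate absorbs by design
    case_length_tilt: float = 0.0
    dup_fraction: float = 0.75
    de_novo_fraction_b: float = 0.10

    def __post_init__(self) -> None:
        if min(self.n_chrom, self.chrom_length, self.n_genes + 1, self.n_pathways + 1) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.clustered_fraction <= 1:
            raise ValueError("clustered_fraction must be in [0, 1]")
        for pid, ba, bb in self.planted_pathways:
            if ba < 1 or bb < 1:
                raise ValueError(f"boosts must be >= 1 (pathway {pid})")

    @property
    def genome_length(self) -> int:
        return self.n_chrom * self.chrom_length

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


def _rng_for(scenario: SimulationScenario, stream: str) -> np.random.Generator:
    # independent named streams so genome / pathways / CNVs don't interact
    root = np.random.SeedSequence(scenario.seed)
    offset = {"genome": 0, "pathways": 1, "cnvs": 2}[stream]
    return np.random.default_rng(root.spawn(3)[offset])


def simulate_genome(scenario: SimulationScenario) -> set[GeneInterval]:
    """Place disjoint genes on each chromosome (deterministic under seed).

    With ``gene_cluster_fraction`` 0 (the default) genes are spread
    uniformly. A positive fraction lays that share of genes down in tight
    runs of ``gene_cluster_size`` adjacent genes — gene-dense islands like
    those real genomes have, which make gene load vary sharply with CNV
    position.
    """
    rng = _rng_for(scenario, "genome")
    if scenario.n_genes == 0:
        return set()
    per_chrom = np.full(scenario.n_chrom, scenario.n_genes // scenario.n_chrom)
    per_chrom[: scenario.n_genes % scenario.n_chrom] += 1
    genes: set[GeneInterval] = set()
    gid = 0
    for ci, chrom in enumerate(scenario.chrom_names()):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = rng.integers(
            max(1, scenario.gene_length // 2),
            scenario.gene_length + scenario.gene_length // 2 + 1,
            size=n,
        )
        # group genes into blocks: clustered runs plus singletons, shuffled
        n_clustered = int(round(scenario.gene_cluster_fraction * n))
        run = max(2, scenario.gene_cluster_size)
        blocks: list[int] = []  # block sizes in genome order
        left = n_clustered
        while left > 0:
            blocks.append(min(run, left))
            left -= min(run, left)
        blocks.extend([1] * (n - n_clustered))
        blocks_arr = np.array(blocks)
        rng.shuffle(blocks_arr)
        within_gap = max(1, scenario.gene_length // 5)
        total_within = int(((blocks_arr - 1) * within_gap).sum())
        slack = scenario.chrom_length - int(lengths.sum()) - total_within
        if slack <= 0:
            raise ValueError("gene density infeasible: genes do not fit chromosome")
        block_gaps = np.sort(rng.integers(0, slack + 1, size=len(blocks_arr)))
        k = 0
        prev_gap = 0
        starts = np.empty(n, dtype=np.int64)
        cursor = 1
        for b, gap in zip(blocks_arr, block_gaps):
            cursor += int(gap) - prev_gap  # block_gaps are cumulative draws
            prev_gap = int(gap)
            for j in range(int(b)):
                starts[k] = cursor
                cursor += int(lengths[k])
                if j < int(b) - 1:
                    cursor += within_gap
                k += 1
        for k in range(n):
            genes.add(
                GeneInterval(
                    f"G{gid:05d}", chrom, int(starts[k]), int(starts[k] + lengths[k] - 1)
                )
            )
            gid += 1
    return genes


def _ordered(genes: set[GeneInterval]) -> list[GeneInterval]:
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def simulate_pathways(
    scenario: SimulationScenario, genes: set[GeneInterval]
) -> PathwayDB:
    """Random gene sets, a fraction drawn from contiguous genomic windows.

    Clustered pathways model gene families sitting side by side on the
    genome — the situation in which one CNV hits many genes of the same
    pathway and a count-based test overstates the evidence.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    rng = _rng_for(scenario, "pathways")
    ordered = _ordered(genes)
    n_genes = len(ordered)
    lo, hi = scenario.pathway_size_range
    if hi > n_genes:
        raise ValueError("pathway size exceeds number of genes")
    sizes = rng.integers(lo, hi + 1, size=scenario.n_pathways)
    n_clustered = int(round(scenario.clustered_fraction * scenario.n_pathways))
    clustered_flags = np.zeros(scenario.n_pathways, dtype=bool)
    clustered_flags[:n_clustered] = True
    rng.shuffle(clustered_flags)

    db = PathwayDB()
    used: set[int] = set()

    def window_candidates(w: range, size: int) -> list[int] | None:
        # a clustered window must sit on one chromosome; in a disjoint
        # database only the sampled genes are reserved, so the window just
        # needs enough unused genes left in it
        if ordered[w[0]].chrom != ordered[w[-1]].chrom:
            return None
        pool = [j for j in w if j not in used] if scenario.disjoint_pathways else list(w)
        return pool if len(pool) >= size else None

    def free_window(size: int) -> list[int]:
        span = min(n_genes, max(size, scenario.cluster_window_genes))
        for _ in range(1000):
            s = int(rng.integers(0, n_genes - span + 1))
            pool = window_candidates(range(s, s + span), size)
            if pool is not None:
                return sorted(int(j) for j in rng.choice(pool, size=size, replace=False))
        for s in range(n_genes - span + 1):  # deterministic fallback scan
            pool = window_candidates(range(s, s + span), size)
            if pool is not None:
                return sorted(int(j) for j in rng.choice(pool, size=size, replace=False))
        raise ValueError("no free contiguous window left for clustered pathway")

    # clustered pathways are allocated first: they need contiguous index
    # runs, which scattered random draws would otherwise fragment
    members: dict[int, list[int]] = {}
    order = sorted(range(scenario.n_pathways), key=lambda i: not clustered_flags[i])
    for i in order:
        size = int(sizes[i])
        if clustered_flags[i]:
            idxs = free_window(size)
        else:
            pool = (
                sorted(set(range(n_genes)) - used)
                if scenario.disjoint_pathways
                else list(range(n_genes))
            )
            if len(pool) < size:
                raise ValueError("not enough unused genes for disjoint pathways")
            idxs = [int(j) for j in rng.choice(pool, size=size, replace=False)]
        if scenario.disjoint_pathways:
            used.update(idxs)
        members[i] = idxs
    for i in range(scenario.n_pathways):
        db.add(
            f"PW{i:03d}",
            {ordered[j].gene_id for j in members[i]},
            description="clustered" if clustered_flags[i] else "random",
            source="synthetic",
        )
    return db


def _baseline_hit_prob(
    scenario: SimulationScenario, pathway_genes: Sequence[GeneInterval]
) -> float:
    """Approximate null probability that one CNV hits >=1 pathway gene."""
    p_miss = 1.0
    for g in pathway_genes:
        p_gene = min(1.0, (g.length + scenario.cnv_length_median) / scenario.genome_length)
        p_miss *= 1.0 - p_gene
    return 1.0 - p_miss


def _draw_length(
    scenario: SimulationScenario, rng: np.random.Generator, tilt: float = 0.0
) -> int:
    """One CNV length from the truncated log-normal law.

    A positive ``tilt`` reweights the law by exp(tilt * length_Mb)
    (self-normalized over a candidate batch), used for case CNVs.
    """
    mu = np.log(scenario.cnv_length_median)
    upper = scenario.chrom_length // 2
    for _ in range(1000):
        cand = np.exp(rng.normal(mu, scenario.cnv_length_sigma, size=64))
        cand = cand[(cand > scenario.cnv_min_length) & (cand < upper)]
        if len(cand) == 0:
            continue
        if tilt == 0.0:
            return int(cand[0])
        w = np.exp(tilt * (cand - cand.max()) / 1e6)
        return int(rng.choice(cand, p=w / w.sum()))
    raise ValueError("cnv_length_law cannot produce lengths above the minimum")


def simulate_cnvs(
    scenario: SimulationScenario,
    genes: set[GeneInterval],
    db: PathwayDB,
) -> list[CnvRecord]:
    """Both cohorts' case and control CNVs (deterministic under the seed)."""
    rng = _rng_for(scenario, "cnvs")
    by_id = {g.gene_id: g for g in genes}
    chroms = scenario.chrom_names()
    ordered = _ordered(genes)

    planted: dict[str, tuple[float, float, list[GeneInterval]]] = {}
    for pid, boost_a, boost_b in scenario.planted_pathways:
        if pid not in db:
            raise ValueError(f"planted pathway {pid!r} not in db")
        pw_genes = [by_id[g] for g in sorted(db.genes(pid))]
        p0 = _baseline_hit_prob(scenario, pw_genes)
        # re-anchor probability q making the case hit rate q + (1-q) p0
        # equal boost * p0 (capped at 1)
        q_a = min(1.0, max(0.0, (boost_a - 1.0) * p0 / (1.0 - p0)))
        q_b = min(1.0, max(0.0, (boost_b - 1.0) * p0 / (1.0 - p0)))
        planted[pid] = (q_a, q_b, pw_genes)

    shared_anchors: list[GeneInterval] = []
    if scenario.shared_locus_rate > 0 and ordered:
        idxs = rng.choice(len(ordered), size=min(scenario.n_shared_loci, len(ordered)), replace=False)
        shared_anchors = [ordered[i] for i in sorted(idxs)]

    def place_uniform(length: int) -> tuple[str, int]:
        chrom = chroms[int(rng.integers(0, scenario.n_chrom))]
        start = int(rng.integers(1, scenario.chrom_length - length + 2))
        return chrom, start

    def place_over_gene(gene: GeneInterval, length: int) -> tuple[str, int]:
        lo = max(1, gene.start - length + 1)
        hi = min(gene.end, scenario.chrom_length - length + 1)
        if hi < lo:
            hi = lo
        return gene.chrom, int(rng.integers(lo, hi + 1))

    records: list[CnvRecord] = []
    row_index = {"A": 0, "B": 0}
    for cohort, n_case, n_ctrl in (
        ("A", scenario.n_case_a, scenario.n_ctrl_a),
        ("B", scenario.n_case_b, scenario.n_ctrl_b),
    ):
        for label, n in ((Label.CASE, n_case), (Label.CONTROL, n_ctrl)):
            tilt = scenario.case_length_tilt if label is Label.CASE else 0.0
            for _ in range(n):
                length = _draw_length(scenario, rng, tilt)
                chrom, start = place_uniform(length)
                if label is Label.CASE:
                    anchored = False
                    for pid, (q_a, q_b, pw_genes) in planted.items():
                        q = q_a if cohort == "A" else q_b
                        if q > 0 and rng.random() < q:
                            gene = pw_genes[int(rng.integers(0, len(pw_genes)))]
                            chrom, start = place_over_gene(gene, length)
                            anchored = True
                            break
                    if not anchored and shared_anchors and rng.random() < scenario.shared_locus_rate:
                        gene = shared_anchors[int(rng.integers(0, len(shared_anchors)))]
                        chrom, start = place_over_gene(gene, length)
                        anchored = True
                    if not anchored and rng.random() < scenario.case_gene_anchor_rate:
                        gene = ordered[int(rng.integers(0, len(ordered)))]
                        chrom, start = place_over_gene(gene, length)
                cnv_type = (
                    CnvType.DUPLICATION
                    if rng.random() < scenario.dup_fraction
                    else CnvType.DELETION
                )
                if cohort == "B" and label is Label.CASE:
                    inheritance = (
                        Inheritance.DE_NOVO
                        if rng.random() < scenario.de_novo_fraction_b
                        else Inheritance.INHERITED
                    )
                else:
                    inheritance = Inheritance.UNKNOWN
                idx = row_index[cohort]
                row_index[cohort] += 1
                records.append(
                    CnvRecord(
                        cnv_id=f"{cohort}:{idx}",
                        sample_id=f"{cohort}{'P' if label is Label.CASE else 'C'}{idx:04d}",
                        chrom=chrom,
                        start=start,
                        end=start + length - 1,
                        cnv_type=cnv_type,
                        label=label,
                        cohort=cohort,
                        inheritance=inheritance,
                    )
                )
    return records


def simulate_study(
    scenario: SimulationScenario,
) -> tuple[set[GeneInterval], PathwayDB, list[CnvRecord]]:
    """Genome, pathways and CNVs in one call."""
    genes = simulate_genome(scenario)
    db = simulate_pathways(scenario, genes)
    cnvs = simulate_cnvs(scenario, genes, db)
    return genes, db, cnvs


def scenario_presets() -> dict[str, SimulationScenario]:
    """Named study conditions used throughout tests and examples.

    * ``null`` — no planted signal anywhere; calibration baseline.
    * ``planted_shared`` — one pathway boosted 8x in both cohorts.
    * ``planted_disjoint`` — different pathways boosted in each cohort.
    * ``clustered_null`` — half the pathways physically clustered and a
      pathway-agnostic case gene-load (re-anchor rate 0.3), no pathway
      boost: the false-positive control the binary-hit design targets.
    """
    base = SimulationScenario(seed=2014)
    return {
        "null": base,
        "planted_shared": replace(
            base,
            planted_pathways=(("PW000", 8.0, 8.0),),
            shared_locus_rate=0.4,
            n_shared_loci=5,
        ),
        "planted_disjoint": replace(
            base, planted_pathways=(("PW000", 8.0, 1.0), ("PW001", 1.0, 8.0))
        ),
        "clustered_null": replace(
            base,
            clustered_fraction=0.5,
            case_length_tilt=2.0,
        ),
    }
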