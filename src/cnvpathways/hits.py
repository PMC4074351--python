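"""CNV-to-gene hit assignment and regression design construction.

A CNV "hits" a gene if any part of the CNV lies within the gene's
longest-transcript span — i.e. the two closed intervals share at least one
base on the same chromosome.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import CnvRecord, DesignRow, GeneInterval, Label, PathwayDB


@dataclass
class HitIndex:
    """Bidirectional CNV <-> gene hit mapping (mutually consistent)."""

    cnv_to_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_to_cnvs: dict[str, set[str]] = field(default_factory=dict)

    def genes_hit(self, cnv_id: str) -> set[str]:
        return self.cnv_to_genes.get(cnv_id, set())

    def cnvs_hitting(self, gene_id: str) -> set[str]:
        return self.gene_to_cnvs.get(gene_id, set())

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("cnv_id\tgene_id\n")
            for cnv_id in sorted(self.cnv_to_genes):
                for gene_id in sorted(self.cnv_to_genes[cnv_id]):
                    fh.write(f"{cnv_id}\t{gene_id}\n")


def build_gene_trees(genes: Iterable[GeneInterval]) -> dict[str, IntervalTree]:
    """One interval tree per chromosome; closed gene interval [s, e] is
    stored as the half-open [s, e+1) the tree expects."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom].addi(g.start, g.end + 1, g.gene_id)
    return dict(trees)


def build_hit_index(
    cnvs: Sequence[CnvRecord], genes: Iterable[GeneInterval]
) -> HitIndex:
    """Assign gene hits to every CNV (>=1 bp closed-interval overlap)."""
    trees = build_gene_trees(genes)
    index = HitIndex()
    for c in cnvs:
        hit: set[str] = set()
        tree = trees.get(c.chrom)
        if tree is not None:
            hit = {iv.data for iv in tree.overlap(c.start, c.end + 1)}
        index.cnv_to_genes[c.cnv_id] = hit
        for gid in hit:
            index.gene_to_cnvs.setdefault(gid, set()).add(c.cnv_id)
    return index


def build_design(
    cnvs: Sequence[CnvRecord],
    index: HitIndex,
    pathway_genes: set[str],
) -> list[DesignRow]:
    """One covariate row per CNV for the given pathway.

    CNVs hitting zero genes still contribute rows (genes_outside=0,
    pathway_hit=0): they carry information through the length covariate.
    """
    rows: list[DesignRow] = []
    for c in cnvs:
        hit_genes = index.genes_hit(c.cnv_id)
        in_pathway = len(hit_genes & pathway_genes)
        rows.append(
            DesignRow(
                cnv_id=c.cnv_id,
                label=1 if c.label is Label.CASE else 0,
                cnv_length=c.length,
                genes_outside=len(hit_genes) - in_pathway,
                pathway_hit=1 if in_pathway else 0,
                cohort=c.cohort,
            )
        )
    return rows


def pathway_hit_counts(
    cnvs: Sequence[CnvRecord], index: HitIndex, db: PathwayDB
) -> dict[str, int]:
    """Number of CNVs (cases + controls) hitting >=1 gene of each pathway.

    A CNV hitting several genes of one pathway still counts once — the same
    binary-per-CNV definition the regression uses.
    """
    gene_cnvs = {g: index.cnvs_hitting(g) for g in db.all_genes()}
    counts: dict[str, int] = {}
    for pid in db:
        hitters: set[str] = set()
        for g in db.genes(pid):
            hitters |= gene_cnvs.get(g, set())
        counts[pid] = len(hitters)
    return counts


def write_design_tsv(rows: Sequence[DesignRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cnv_id\tlabel\tcnv_length\tgenes_outside\tpathway_hit\tcohort\n")
        for r in sorted(rows, key=lambda r: r.cnv_id):
            fh.write(
                f"{r.cnv_id}\t{r.label}\t{r.cnv_length}\t"
                f"{r.genes_outside}\t{r.pathway_hit}\t{r.cohort}\n"
            )
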