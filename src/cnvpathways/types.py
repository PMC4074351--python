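"""Domain types for CNV pathway-enrichment analysis.

All genomic coordinates are 1-based and inclusive on both ends (NCBI-style).
Dialect conversion (e.g. BED's 0-based half-open convention) happens at the
I/O boundary, never inside analysis code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


def normalize_chrom(chrom: str) -> str:
    """Canonicalize a chromosome name to the ``chr``-prefixed form.

    Mixed naming ("16" vs "chr16") is common across CNV tables and gene
    annotations; everything internal uses one convention.
    """
    chrom = chrom.strip()
    if not chrom:
        raise ValueError("chromosome name must be non-empty")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


class CnvType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class Label(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Inheritance(str, enum.Enum):
    DE_NOVO = "de_novo"
    INHERITED = "inherited"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class GeneInterval:
    """The longest-transcript span of one gene (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnvRecord:
    """One CNV call with its case/control label and cohort of origin.

    ``cohort`` "A" is the first disorder cohort plus its matched controls,
    "B" the second; ``length`` is always ``end - start + 1``.
    """

    cnv_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: CnvType
    label: Label
    cohort: str
    inheritance: Inheritance = Inheritance.UNKNOWN

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"CNV {self.cnv_id}: start {self.start} > end {self.end}"
            )
        if self.cohort not in ("A", "B"):
            raise ValueError(f"CNV {self.cnv_id}: cohort must be 'A' or 'B'")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff ≥1 bp overlap with the closed interval [start, end]."""
        return self.chrom == chrom and self.start <= end and self.end >= start


@dataclass
class PathwayDB:
    """Named gene sets with a provenance tag per pathway."""

    pathways: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def add(
        self,
        pathway_id: str,
        genes: Iterable[str],
        description: str = "",
        source: str = "synthetic",
    ) -> None:
        if pathway_id in self.pathways:
            raise ValueError(f"duplicate pathway_id {pathway_id!r}")
        gene_set = set(genes)
        if not gene_set:
            raise ValueError(f"pathway {pathway_id!r} has an empty gene set")
        self.pathways[pathway_id] = gene_set
        self.descriptions[pathway_id] = description
        self.sources[pathway_id] = source

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.pathways))

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.pathways

    def genes(self, pathway_id: str) -> set[str]:
        return self.pathways[pathway_id]

    def subset(self, pathway_ids: Iterable[str]) -> "PathwayDB":
        ids = set(pathway_ids)
        return PathwayDB(
            pathways={k: set(v) for k, v in self.pathways.items() if k in ids},
            descriptions={k: v for k, v in self.descriptions.items() if k in ids},
            sources={k: v for k, v in self.sources.items() if k in ids},
        )

    def restrict_genes(self, keep: set[str]) -> "PathwayDB":
        """Intersect every gene set with ``keep``, dropping emptied pathways."""
        out = PathwayDB()
        for pid in self:
            genes = self.pathways[pid] & keep
            if genes:
                out.add(pid, genes, self.descriptions[pid], self.sources[pid])
        return out

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.pathways.values():
            out |= genes
        return out


@dataclass(frozen=True)
class Region:
    """A genomic interval in bases (1-based inclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))


RegionList = tuple[Region, ...]


@dataclass(frozen=True)
class DesignRow:
    """Per-CNV covariates for the enrichment regression.

    ``genes_outside`` counts genes the CNV hits that are not in the tested
    pathway; ``pathway_hit`` is 1 iff the CNV hits at least one pathway gene
    (binary by design, not a gene count).
    """

    cnv_id: str
    label: int  # case=1, control=0
    cnv_length: int  # bases
    genes_outside: int
    pathway_hit: int
    cohort: str  # "A" or "B"


def validate_design_rows(rows: Iterable[DesignRow]) -> None:
    for r in rows:
        if r.label not in (0, 1) or r.pathway_hit not in (0, 1):
            raise ValueError(f"invalid design row for {r.cnv_id}")
        if r.genes_outside < 0 or r.cnv_length <= 0:
            raise ValueError(f"invalid design row for {r.cnv_id}")


def mb(x: float) -> int:
    """Convert a megabase coordinate to bases (exact 1e6 scaling)."""
    return int(round(x * 1_000_000))
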