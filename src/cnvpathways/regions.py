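"""Built-in exclusion regions: 14 autism susceptibility loci.

These loci were implicated by earlier CNV studies of autism; secondary
analyses remove genes (or whole CNVs) falling in them to ask whether
cross-disorder pathway overlap survives outside known shared regions.
Coordinates are published in megabases to two decimals; they are scaled by
exactly 1e6, and the single point locus on chromosome 4 becomes a 1-bp
interval (no width is given for it).
"""

from __future__ import annotations

from pathlib import Path

from .types import Region, RegionList, mb

# (chrom, start Mb, end Mb); the chr4 locus is a point.
_AUTISM_LOCI_MB: tuple[tuple[str, float, float], ...] = (
    ("chr1", 174.1, 175.1),
    ("chr2", 13.12, 13.16),
    ("chr2", 49.99, 51.12),
    ("chr3", 2.11, 3.08),
    ("chr3", 4.37, 4.49),
    ("chr3", 122.83, 122.87),
    ("chr3", 174.59, 175.49),
    ("chr4", 144.85, 144.85),
    ("chr6", 161.68, 163.07),
    ("chr7", 68.69, 69.88),
    ("chr10", 87.33, 88.12),
    ("chr15", 23.12, 23.24),
    ("chr16", 29.55, 30.08),
    ("chr22", 49.44, 49.52),
)


def builtin_exclusion_regions() -> RegionList:
    """The 14 autism loci as 1-based inclusive intervals in bases."""
    return tuple(Region(c, mb(s), mb(e)) for c, s, e in _AUTISM_LOCI_MB)


def read_region_list(path: str | Path) -> RegionList:
    """Read a 3-column TSV (chrom, start, end) of regions in bases."""
    regions: list[Region] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append(Region(chrom, int(start), int(end)))
    return tuple(regions)
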