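"""Readers and writers for gene tables, GMT pathway files, and CNV tables.

Gene annotations come in either BED4 (0-based half-open) or a 1-based
inclusive TSV; both are converted to the internal 1-based inclusive
convention on read. CNV tables are a PLINK-``.cnv``-like TSV with a header.
Writers emit the same dialects so round trips are lossless.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from .types import (
    CnvRecord,
    CnvType,
    GeneInterval,
    Inheritance,
    Label,
    PathwayDB,
)


class ParseError(ValueError):
    """Malformed input line; carries the path and line number."""

    def __init__(self, path: Path | str, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


_CNV_TYPE_TOKENS = {
    "del": CnvType.DELETION,
    "deletion": CnvType.DELETION,
    "dup": CnvType.DUPLICATION,
    "duplication": CnvType.DUPLICATION,
}
_LABEL_TOKENS = {"case": Label.CASE, "control": Label.CONTROL}
_INHERITANCE_TOKENS = {
    "de_novo": Inheritance.DE_NOVO,
    "denovo": Inheritance.DE_NOVO,
    "inherited": Inheritance.INHERITED,
    "unknown": Inheritance.UNKNOWN,
    "": Inheritance.UNKNOWN,
}


def read_gene_table(path: str | Path, dialect: str = "tsv1") -> set[GeneInterval]:
    """Read gene spans from BED4 (``bed``) or 1-based TSV (``tsv1``).

    BED intervals (0-based half-open) become 1-based inclusive: (s, e) ->
    (s+1, e). Duplicate gene_ids are rejected.
    """
    if dialect not in ("bed", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    genes: dict[str, GeneInterval] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, f"expected 4 fields, got {len(fields)}")
            try:
                if dialect == "bed":
                    chrom, s, e, gid = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    start, end = s + 1, e
                else:
                    gid, chrom, start, end = (
                        fields[0],
                        fields[1],
                        int(fields[2]),
                        int(fields[3]),
                    )
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad coordinate: {exc}") from exc
            if gid in genes:
                raise ParseError(path, lineno, f"duplicate gene_id {gid!r}")
            try:
                genes[gid] = GeneInterval(gid, chrom, start, end)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return set(genes.values())


def write_gene_table(
    genes: Iterable[GeneInterval], path: str | Path, dialect: str = "tsv1"
) -> None:
    if dialect not in ("bed", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("w") as fh:
        for g in sorted(genes):
            if dialect == "bed":
                fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
            else:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\n")


def read_gmt(path: str | Path) -> PathwayDB:
    """Read a GMT file: one pathway per line as name, description, genes."""
    path = Path(path)
    db = PathwayDB()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    path, lineno, f"GMT line needs >=3 fields, got {len(fields)}"
                )
            pid, desc = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            try:
                db.add(pid, genes, description=desc, source="gmt")
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return db


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid in db:
            genes = "\t".join(sorted(db.genes(pid)))
            fh.write(f"{pid}\t{db.descriptions.get(pid, '')}\t{genes}\n")


_CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "label", "cohort", "inheritance"]


def read_cnv_table(path: str | Path) -> list[CnvRecord]:
    """Read a CNV TSV with header; cnv_id is assigned as <cohort>:<row-index>.

    The ``inheritance`` column is optional and defaults to ``unknown``.
    """
    path = Path(path)
    records: list[CnvRecord] = []
    row_index: dict[str, int] = {}
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = [c for c in _CNV_COLUMNS[:7] if c not in reader.fieldnames]
        if missing:
            raise ParseError(path, 1, f"missing columns: {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            type_tok = row["type"].strip().lower()
            if type_tok not in _CNV_TYPE_TOKENS:
                raise ParseError(path, lineno, f"unknown CNV type token {row['type']!r}")
            label_tok = row["label"].strip().lower()
            if label_tok not in _LABEL_TOKENS:
                raise ParseError(path, lineno, f"unknown label token {row['label']!r}")
            inh_tok = (row.get("inheritance") or "").strip().lower()
            if inh_tok not in _INHERITANCE_TOKENS:
                raise ParseError(
                    path, lineno, f"unknown inheritance token {row['inheritance']!r}"
                )
            cohort = row["cohort"].strip()
            idx = row_index.get(cohort, 0)
            row_index[cohort] = idx + 1
            try:
                records.append(
                    CnvRecord(
                        cnv_id=f"{cohort}:{idx}",
                        sample_id=row["sample_id"].strip(),
                        chrom=row["chrom"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        cnv_type=_CNV_TYPE_TOKENS[type_tok],
                        label=_LABEL_TOKENS[label_tok],
                        cohort=cohort,
                        inheritance=_INHERITANCE_TOKENS[inh_tok],
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return records


def write_cnv_table(cnvs: Iterable[CnvRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CNV_COLUMNS) + "\n")
        for c in cnvs:
            type_tok = "del" if c.cnv_type is CnvType.DELETION else "dup"
            fh.write(
                "\t".join(
                    [
                        c.sample_id,
                        c.chrom,
                        str(c.start),
                        str(c.end),
                        type_tok,
                        c.label.value,
                        c.cohort,
                        c.inheritance.value,
                    ]
                )
                + "\n"
            )
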