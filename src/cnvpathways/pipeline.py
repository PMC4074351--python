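"""End-to-end orchestration and publication-style reports.

``run_pipeline`` sequences the primary analysis (per-cohort enrichment,
cross-disorder replication grid, combined meta-analysis) and the optional
secondary variants (region exclusion, cross-overlap removal, del/dup
subsets), writing machine-readable TSVs plus human-readable grids. All
machine-readable output is fully determined by the resolved config and the
seed. Human tables use a "<.001"-style display for zero permutation
numerators; TSVs always carry raw floats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .cross_disorder import Table1Cell, format_table1, run_table1_grid
from .enrichment import (
    EnrichmentResult,
    significant_genes_in_pathway,
    test_all_pathways,
    test_single_genes,
)
from .filters import (
    FilterConfig,
    exclude_region_genes,
    filter_by_frequency,
    filter_by_length,
    filter_pathways,
    remove_cross_overlapping_case_cnvs,
    subset_by_type,
)
from .hits import HitIndex, build_hit_index, pathway_hit_counts
from .io import read_cnv_table, read_gene_table, read_gmt
from .physical_overlap import overlap_regression
from .regions import builtin_exclusion_regions, read_region_list
from .simulate import scenario_presets, simulate_study
from .types import CnvRecord, CnvType, GeneInterval, Label, PathwayDB, RegionList


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    out_dir: str = "results"
    # inputs: either file paths ...
    genes_path: str | None = None
    genes_dialect: str = "tsv1"
    gmt_path: str | None = None
    cnv_paths: tuple[str, ...] = ()
    # ... or a synthetic preset
    preset: str | None = None
    # per-cohort total sample counts for the frequency filter
    n_samples_a: int = 0
    n_samples_b: int = 0
    apply_frequency_filter: bool = False
    filters: FilterConfig = field(default_factory=FilterConfig)
    # secondary-analysis toggles
    exclude_regions: str | None = None  # None, "builtin" or a path
    remove_overlapping: bool = False
    type_subset: str | None = None  # None, "del" or "dup"
    # cross-disorder permutation
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    n_perm: int = 1000
    seed: int = 0
    top_k: int = 20

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["filters"] = dataclasses.asdict(self.filters)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "filters" in data:
            data["filters"] = FilterConfig(**data["filters"])
        for key in ("cnv_paths", "alphas"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def results_to_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "pathway_id\tn_case_hits\tn_control_hits\tcoefficient\t"
            "deviance_drop\tp_one_sided\tmethod\tconverged\n"
        )
        for r in results:
            fh.write(
                f"{r.pathway_id}\t{r.n_case_hits}\t{r.n_control_hits}\t"
                f"{r.coefficient:.6g}\t{r.deviance_drop:.6g}\t"
                f"{r.p_one_sided:.6g}\t{r.method}\t{int(r.converged)}\n"
            )


def _display_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3g}"


def gene_hit_summary(
    cnvs: Sequence[CnvRecord], index: HitIndex, pathway_genes: set[str]
) -> tuple[int, int]:
    """(unique pathway genes hit by case CNVs, case CNV x gene incidences).

    Both counts are reported because "number of gene hits" is ambiguous
    between them.
    """
    unique: set[str] = set()
    incidences = 0
    for c in cnvs:
        if c.label is not Label.CASE:
            continue
        hit = index.genes_hit(c.cnv_id) & pathway_genes
        unique |= hit
        incidences += len(hit)
    return len(unique), incidences


def format_table2(
    combined: Sequence[EnrichmentResult],
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    gene_results: Sequence[EnrichmentResult],
    db: PathwayDB,
    cnvs: Sequence[CnvRecord],
    index: HitIndex,
    k: int = 20,
    alpha: float = 0.05,
) -> str:
    """Top-k combined-analysis pathways among those enriched in BOTH cohorts.

    Qualifying set: p < alpha in cohort A and in cohort B; rows sorted by
    combined p, ties broken by pathway_id. Gene-hit columns give unique
    genes hit / CNVxgene incidences for case CNVs, per cohort and combined.
    """
    p_a = {r.pathway_id: r.p_one_sided for r in results_a}
    p_b = {r.pathway_id: r.p_one_sided for r in results_b}
    qualifying = [
        r
        for r in combined
        if p_a.get(r.pathway_id, 1.0) < alpha and p_b.get(r.pathway_id, 1.0) < alpha
    ]
    qualifying.sort(key=lambda r: (r.p_one_sided, r.pathway_id))
    rows = qualifying[:k]
    cnvs_a = [c for c in cnvs if c.cohort == "A"]
    cnvs_b = [c for c in cnvs if c.cohort == "B"]
    lines = [
        f"# {len(qualifying)} pathways enriched (p < {alpha:g}) in both cohorts; top {len(rows)} by combined p",
        "pathway_id\tn_genes\thits_combined(u/i)\thits_A(u/i)\thits_B(u/i)\t"
        "p_combined\tp_A\tp_B\tsignificant_genes\tdescription",
    ]
    for r in rows:
        genes = db.genes(r.pathway_id)
        uc, ic = gene_hit_summary(cnvs, index, genes)
        ua, ia = gene_hit_summary(cnvs_a, index, genes)
        ub, ib = gene_hit_summary(cnvs_b, index, genes)
        sig = significant_genes_in_pathway(genes, gene_results, alpha)
        lines.append(
            f"{r.pathway_id}\t{len(genes)}\t{uc}/{ic}\t{ua}/{ia}\t{ub}/{ib}\t"
            f"{r.p_one_sided:.3g}\t{_display_p(p_a[r.pathway_id])}\t"
            f"{_display_p(p_b[r.pathway_id])}\t{','.join(sig) or '-'}\t"
            f"{db.descriptions.get(r.pathway_id, '')}"
        )
    return "\n".join(lines)


def _load_regions(spec: str | None) -> RegionList:
    if spec is None:
        return ()
    if spec == "builtin":
        return builtin_exclusion_regions()
    return read_region_list(spec)


@dataclass
class ReportBundle:
    out_dir: Path
    genes: set[GeneInterval]
    db: PathwayDB
    cnvs: list[CnvRecord]
    results_a: list[EnrichmentResult]
    results_b: list[EnrichmentResult]
    results_combined: list[EnrichmentResult]
    table1: list[Table1Cell]
    table2_text: str
    log: list[str]


def run_pipeline(config: RunConfig) -> ReportBundle:
    log: list[str] = [f"cnvpathways {__version__}", f"seed {config.seed}"]

    # ---- load or simulate inputs -------------------------------------
    try:
        if config.preset is not None:
            presets = scenario_presets()
            if config.preset not in presets:
                raise ValueError(f"unknown preset {config.preset!r}")
            scenario = dataclasses.replace(presets[config.preset], seed=config.seed)
            genes, db, cnvs = simulate_study(scenario)
            log.append(f"simulated preset {config.preset}")
        else:
            if not (config.genes_path and config.gmt_path and config.cnv_paths):
                raise ValueError("need genes_path, gmt_path and cnv_paths (or a preset)")
            genes = read_gene_table(config.genes_path, config.genes_dialect)
            db = read_gmt(config.gmt_path)
            cnvs = []
            for p in config.cnv_paths:
                cnvs.extend(read_cnv_table(p))
    except (OSError, ValueError) as exc:
        raise PipelineError("load", str(exc)) from exc
    log.append(f"inputs: {len(genes)} genes, {len(db)} pathways, {len(cnvs)} CNVs")

    # ---- CNV-level filters -------------------------------------------
    try:
        cnvs = filter_by_length(cnvs, config.filters.min_cnv_length)
        log.append(f"after length filter (> {config.filters.min_cnv_length}): {len(cnvs)} CNVs")
        if config.apply_frequency_filter:
            kept: list[CnvRecord] = []
            for cohort, n_samples in (("A", config.n_samples_a), ("B", config.n_samples_b)):
                subset = [c for c in cnvs if c.cohort == cohort]
                kept.extend(
                    filter_by_frequency(
                        subset,
                        total_samples=n_samples,
                        max_freq=config.filters.max_frequency,
                        ro=config.filters.reciprocal_overlap_for_frequency,
                    )
                )
            cnvs = kept
            log.append(f"after frequency filter (< {config.filters.max_frequency}): {len(cnvs)} CNVs")
        if config.type_subset is not None:
            cnv_type = CnvType.DELETION if config.type_subset == "del" else CnvType.DUPLICATION
            cnvs = subset_by_type(cnvs, cnv_type)
            log.append(f"after {config.type_subset} subset: {len(cnvs)} CNVs")
        if config.remove_overlapping:
            cases_a = [c for c in cnvs if c.cohort == "A" and c.label is Label.CASE]
            cases_b = [c for c in cnvs if c.cohort == "B" and c.label is Label.CASE]
            surv_a, surv_b = remove_cross_overlapping_case_cnvs(cases_a, cases_b)
            keep_ids = {c.cnv_id for c in surv_a} | {c.cnv_id for c in surv_b}
            cnvs = [
                c for c in cnvs if c.label is Label.CONTROL or c.cnv_id in keep_ids
            ]
            log.append(
                f"after cross-overlap removal: {len(surv_a)} A-case and {len(surv_b)} B-case survivors"
            )
        regions = _load_regions(config.exclude_regions)
        if regions:
            genes = exclude_region_genes(genes, regions)
            db = db.restrict_genes({g.gene_id for g in genes})
            log.append(f"after region exclusion: {len(genes)} genes, {len(db)} pathways")
    except (OSError, ValueError) as exc:
        raise PipelineError("filter", str(exc)) from exc

    cnvs_a = [c for c in cnvs if c.cohort == "A"]
    cnvs_b = [c for c in cnvs if c.cohort == "B"]
    if not cnvs_a or not cnvs_b:
        raise PipelineError("filter", "a cohort has no CNVs left after filtering")

    # ---- hit mapping and pathway filter ------------------------------
    try:
        index_all = build_hit_index(cnvs, genes)
        index_a = build_hit_index(cnvs_a, genes)
        index_b = build_hit_index(cnvs_b, genes)
        counts = pathway_hit_counts(cnvs, index_all, db)
        db = filter_pathways(db, config.filters, counts)
        log.append(f"after pathway filter: {len(db)} pathways")
        if len(db) == 0:
            raise ValueError("no pathway passed the size/hit filters")
    except ValueError as exc:
        raise PipelineError("hits", str(exc)) from exc

    # ---- enrichment ---------------------------------------------------
    try:
        results_a = test_all_pathways(cnvs_a, index_a, db)
        results_b = test_all_pathways(cnvs_b, index_b, db)
        results_combined = test_all_pathways(cnvs, index_all, db, include_cohort=True)
        gene_results = test_single_genes(cnvs, index_all, genes, include_cohort=True)
    except ValueError as exc:
        raise PipelineError("enrich", str(exc)) from exc

    # ---- cross-disorder permutation grid ------------------------------
    try:
        table1 = run_table1_grid(
            results_a,
            cnvs_b,
            index_b,
            db,
            alphas=config.alphas,
            n_perm=config.n_perm,
            seed=config.seed,
        )
    except ValueError as exc:
        raise PipelineError("cross", str(exc)) from exc

    table2_text = format_table2(
        results_combined,
        results_a,
        results_b,
        gene_results,
        db,
        cnvs,
        index_all,
        k=config.top_k,
    )

    # ---- physical overlap ---------------------------------------------
    cases_a = [c for c in cnvs_a if c.label is Label.CASE]
    cases_b = [c for c in cnvs_b if c.label is Label.CASE]
    overlap_lines = ["direction\tcoefficient\tp_one_sided\tn_case_overlap\tn_control_overlap"]
    try:
        for direction, x, y in (
            ("A_vs_B_cases", cnvs_a, cases_b),
            ("B_vs_A_cases", cnvs_b, cases_a),
        ):
            r = overlap_regression(x, y, direction)
            overlap_lines.append(
                f"{r.direction}\t{r.coefficient:.6g}\t{r.p_one_sided:.6g}\t"
                f"{r.n_overlapping_case}\t{r.n_overlapping_control}"
            )
    except ValueError as exc:
        raise PipelineError("overlap", str(exc)) from exc

    # ---- write the bundle ---------------------------------------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    results_to_tsv(results_a, out / "enrichment_A.tsv")
    results_to_tsv(results_b, out / "enrichment_B.tsv")
    results_to_tsv(results_combined, out / "enrichment_combined.tsv")
    results_to_tsv(gene_results, out / "enrichment_genes_combined.tsv")
    (out / "table1.txt").write_text(format_table1(table1) + "\n")
    with (out / "table1.tsv").open("w") as fh:
        fh.write("subset\talpha\tjoint_count\tempirical_p\n")
        for c in table1:
            fh.write(
                f"{c.subset}\t{c.alpha:g}\t"
                f"{'' if c.joint_count is None else c.joint_count}\t"
                f"{'' if c.empirical_p is None else format(c.empirical_p, '.6g')}\n"
            )
    (out / "table2.txt").write_text(table2_text + "\n")
    (out / "physical_overlap.tsv").write_text("\n".join(overlap_lines) + "\n")
    (out / "stage_log.txt").write_text("\n".join(log) + "\n")

    return ReportBundle(
        out_dir=out,
        genes=genes,
        db=db,
        cnvs=cnvs,
        results_a=results_a,
        results_b=results_b,
        results_combined=results_combined,
        table1=table1,
        table2_text=table2_text,
        log=log,
    )
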