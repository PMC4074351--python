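"""The CNV and pathway filters, and the secondary-analysis variants.

Shows the inclusion rules (>500 kb, <1% carrier frequency, pathway size
and hit floors), the 14 built-in exclusion regions, and the symmetric
removal of case CNVs that physically overlap the other cohort's cases.
"""

from cnvpathways import (
    FilterConfig,
    Label,
    build_hit_index,
    builtin_exclusion_regions,
    exclude_region_genes,
    filter_by_frequency,
    filter_by_length,
    filter_pathways,
    pathway_hit_counts,
    remove_cross_overlapping_case_cnvs,
    scenario_presets,
    simulate_study,
)

genes, db, cnvs = simulate_study(scenario_presets()["planted_shared"])

large = filter_by_length(cnvs, 500_000)
print(f"{len(cnvs)} CNVs; {len(large)} are large (>500 kb)")

cohort_a = [c for c in large if c.cohort == "A"]
rare_a = filter_by_frequency(cohort_a, total_samples=5_808)
print(f"cohort A: {len(cohort_a)} large CNVs, {len(rare_a)} rare (<1% of 5,808 samples)")

regions = builtin_exclusion_regions()
print(f"\n{len(regions)} built-in exclusion regions, e.g. "
      f"{regions[12].chrom}:{regions[12].start:,}-{regions[12].end:,}")
kept_genes = exclude_region_genes(genes, regions)
print(f"gene set: {len(genes)} -> {len(kept_genes)} after region exclusion "
      "(simulated genome barely intersects the real loci)")

cases_a = [c for c in large if c.cohort == "A" and c.label is Label.CASE]
cases_b = [c for c in large if c.cohort == "B" and c.label is Label.CASE]
surv_a, surv_b = remove_cross_overlapping_case_cnvs(cases_a, cases_b)
print(
    f"\ncross-overlap removal: cohort A cases {len(cases_a)} -> {len(surv_a)}, "
    f"cohort B cases {len(cases_b)} -> {len(surv_b)}"
)
print("(planted shared loci make many case CNVs overlap across cohorts,")
print(" so this secondary analysis removes a sizable share of them)")

index = build_hit_index(large, genes)
filtered = filter_pathways(db, FilterConfig(), pathway_hit_counts(large, index, db))
print(f"\npathway filter: {len(db)} -> {len(filtered)} pathways "
      "(3-1,500 genes and >=10 CNV hits in the total sample)")
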