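"""Simulate a two-cohort CNV study and test every pathway for enrichment.

Builds the planted_shared study (one pathway enriched 8x in both cohorts,
plus shared case loci), applies the pathway filters, and prints the five
most enriched pathways in the combined sample.
"""

from cnvpathways import (
    FilterConfig,
    build_hit_index,
    filter_pathways,
    pathway_hit_counts,
    scenario_presets,
    simulate_study,
    test_all_pathways,
)

genes, db, cnvs = simulate_study(scenario_presets()["planted_shared"])
print(f"simulated {len(genes)} genes, {len(db)} pathways, {len(cnvs)} CNVs")

index = build_hit_index(cnvs, genes)
db = filter_pathways(db, FilterConfig(), pathway_hit_counts(cnvs, index, db))
print(f"{len(db)} pathways pass the 3-1,500 gene / >=10 hit filters")

results = test_all_pathways(cnvs, index, db, include_cohort=True)
results.sort(key=lambda r: (r.p_one_sided, r.pathway_id))
print("\ntop pathways (combined two-cohort analysis):")
print("pathway   case/control hits   coefficient   one-sided p")
for r in results[:5]:
    print(
        f"{r.pathway_id:8s}  {r.n_case_hits:4d} / {r.n_control_hits:4d}"
        f"        {r.coefficient:+.2f}       {r.p_one_sided:.3g}"
    )
print(
    "\nThe planted pathway (PW000) should lead with a tiny p: its case CNV"
    "\nhit rate is 8x baseline while controls stay at baseline. The"
    "\ncoefficient is the log-odds of case status for CNVs hitting the"
    "\npathway, adjusted for CNV length and genes hit elsewhere."
)
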