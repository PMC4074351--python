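"""Physical overlap of case CNVs across cohorts.

Fits overlap ~ case/control + CNV length in each direction: are cohort B's
case CNVs more likely than its control CNVs to physically overlap cohort
A's case CNVs (and vice versa)? Repeats the fit after excluding the 14
built-in susceptibility regions.
"""

from cnvpathways import (
    Label,
    builtin_exclusion_regions,
    overlap_regression,
    scenario_presets,
    simulate_study,
)

_, _, cnvs = simulate_study(scenario_presets()["planted_shared"])
cohort_a = [c for c in cnvs if c.cohort == "A"]
cohort_b = [c for c in cnvs if c.cohort == "B"]
cases_a = [c for c in cohort_a if c.label is Label.CASE]
cases_b = [c for c in cohort_b if c.label is Label.CASE]

for direction, xs, ys in (
    ("A vs B cases", cohort_a, cases_b),
    ("B vs A cases", cohort_b, cases_a),
):
    full = overlap_regression(xs, ys, direction)
    reduced = overlap_regression(
        xs, ys, direction, exclude_regions=builtin_exclusion_regions()
    )
    print(
        f"{direction}: case overlaps {full.n_overlapping_case}, "
        f"control overlaps {full.n_overlapping_control}, "
        f"coef {full.coefficient:+.2f}, one-sided p {full.p_one_sided:.3g} "
        f"(regions excluded: p {reduced.p_one_sided:.3g})"
    )
print(
    "\nA positive coefficient with small p says case CNVs in one cohort"
    "\npreferentially land where the other cohort's case CNVs lie, beyond"
    "\nwhat CNV size alone explains. The planted_shared study draws 40% of"
    "\ncase CNVs from five shared loci, so both directions should reject."
)
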