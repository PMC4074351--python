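"""Physical overlap of case CNVs between cohorts.

Asks whether one cohort's case CNVs are more likely than its control CNVs
to physically overlap the other cohort's case CNVs, via the logistic model

    overlap (0/1) ~ case/control + CNV length

with a one-sided p for a positive case/control coefficient (same signed
deviance convention as the enrichment tests). Overlap is >=1 bp on the same
chromosome, type-agnostic. A positive coefficient indicates case CNVs
preferentially landing where the other disorder's case CNVs lie — shared
loci rather than (or as well as) shared pathways.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enrichment import DevianceTester
from .filters import exclude_region_cnvs
from .types import CnvRecord, Label, RegionList


@dataclass(frozen=True)
class PhysicalOverlapResult:
    direction: str  # "A_vs_B_cases" or "B_vs_A_cases"
    coefficient: float
    p_one_sided: float
    n_overlapping_case: int
    n_overlapping_control: int
    method: str
    converged: bool


def flag_overlaps(
    cnvs_x: Sequence[CnvRecord], case_cnvs_y: Sequence[CnvRecord]
) -> np.ndarray:
    """1 per CNV in X iff it overlaps (>=1 bp) any Y case CNV."""
    by_chrom: dict[str, list[CnvRecord]] = defaultdict(list)
    for y in case_cnvs_y:
        if y.label is Label.CASE:
            by_chrom[y.chrom].append(y)
    flags = np.zeros(len(cnvs_x), dtype=int)
    for i, x in enumerate(cnvs_x):
        if any(x.start <= y.end and x.end >= y.start for y in by_chrom[x.chrom]):
            flags[i] = 1
    return flags


def overlap_regression(
    cnvs_x: Sequence[CnvRecord],
    case_cnvs_y: Sequence[CnvRecord],
    direction: str,
    exclude_regions: RegionList = (),
) -> PhysicalOverlapResult:
    """Fit overlap ~ label + length over cohort X's CNVs.

    With ``exclude_regions``, whole CNVs touching any region are removed
    from X and from Y's case list before flagging (distinct from the
    gene-level exclusion used in the pathway reruns).
    """
    if exclude_regions:
        cnvs_x = exclude_region_cnvs(cnvs_x, exclude_regions)
        case_cnvs_y = exclude_region_cnvs(case_cnvs_y, exclude_regions)
    labels = {c.label for c in cnvs_x}
    if labels != {Label.CASE, Label.CONTROL}:
        raise ValueError("cohort X must contain both case and control CNVs")
    cnvs_x = sorted(cnvs_x, key=lambda c: c.cnv_id)
    flags = flag_overlaps(cnvs_x, case_cnvs_y)
    is_case = np.array([1.0 if c.label is Label.CASE else 0.0 for c in cnvs_x])
    length_kb = np.array([c.length for c in cnvs_x], float) / 1000.0
    # outcome is the overlap flag; the "pathway hit" slot of the shared
    # tester carries the case/control indicator whose coefficient we test
    tester = DevianceTester(length_kb, np.zeros(len(cnvs_x)), is_case)
    coef, _, p, converged, method, _ = tester.test(flags.astype(float))
    if method == "degenerate":
        # all CNVs on one side of the label, or flags constant, handled by
        # the caller contract; constant labels already raise above
        p, coef = 1.0, 0.0
    return PhysicalOverlapResult(
        direction=direction,
        coefficient=coef,
        p_one_sided=p,
        n_overlapping_case=int(flags[is_case == 1].sum()),
        n_overlapping_control=int(flags[is_case == 0].sum()),
        method=method,
        converged=converged,
    )
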