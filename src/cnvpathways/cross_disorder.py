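"""Cross-disorder pathway-overlap test.

Pathways nominally enriched in cohort A (at p < .05, .01 or .001) are
re-tested in cohort B, and the number also enriched in B at the same level
is compared with its distribution when B's case/control labels are randomly
permuted over B's CNVs (label totals preserved). The empirical p is the
proportion of replicates with a joint count at least as large as observed;
a zero numerator is reported as "< 1/n_perm" in formatted output while the
raw proportion stays in the machine-readable result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .enrichment import DevianceTester, EnrichmentResult, PathwaySweep
from .hits import HitIndex
from .types import CnvRecord, Inheritance, Label, PathwayDB


@dataclass(frozen=True)
class OverlapPermutationResult:
    alpha: float
    n_selected: int
    observed_joint: int
    permuted_counts: tuple[int, ...]
    empirical_p: float
    n_perm: int
    seed: int

    def formatted_p(self) -> str:
        if self.empirical_p == 0.0:
            return f"<{1.0 / self.n_perm:.3g}"
        return f"{self.empirical_p:.3g}"


def select_enriched(
    results: Sequence[EnrichmentResult], alpha: float
) -> set[str]:
    """Pathways with one-sided p strictly below alpha."""
    return {r.pathway_id for r in results if r.p_one_sided < alpha}


def count_joint_enriched(
    selected: set[str], results_b: Sequence[EnrichmentResult], alpha: float
) -> int:
    """How many selected pathways are also enriched (p < alpha) in B."""
    by_id = {r.pathway_id: r for r in results_b}
    missing = selected - set(by_id)
    if missing:
        raise ValueError(f"selected pathways missing from B results: {sorted(missing)}")
    return sum(1 for pid in selected if by_id[pid].p_one_sided < alpha)


def _joint_count(
    testers: Sequence[DevianceTester], y: np.ndarray, alpha: float
) -> int:
    count = 0
    for tester in testers:
        _, _, p, _, _, _ = tester.test(y)
        if p < alpha:
            count += 1
    return count


def permutation_overlap_test(
    cnvs_b: Sequence[CnvRecord],
    index_b: HitIndex,
    db: PathwayDB,
    selected: set[str],
    alpha: float,
    n_perm: int = 1000,
    seed: int | None = None,
) -> OverlapPermutationResult:
    """Permutation null for the joint-enrichment count.

    Every replicate permutes B's case/control labels over B's CNVs and
    refits the full deviance test for each selected pathway (no shortcut:
    nuisance coefficients are re-estimated each time).
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not selected:
        raise ValueError("selected pathway set must be non-empty")
    missing = selected - set(db.pathways)
    if missing:
        raise ValueError(f"selected pathways missing from db: {sorted(missing)}")

    sweep = PathwaySweep(cnvs_b, index_b, include_cohort=False)
    testers = [sweep.tester(db.genes(pid))[0] for pid in sorted(selected)]
    y_obs = sweep.y
    observed = _joint_count(testers, y_obs, alpha)

    # one master seed spawning per-replicate streams: replicate r is
    # reproducible in isolation
    streams = np.random.SeedSequence(seed).spawn(n_perm)
    label_multiset = np.sort(y_obs)
    counts: list[int] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        y_perm = rng.permutation(y_obs)
        assert np.array_equal(np.sort(y_perm), label_multiset)
        counts.append(_joint_count(testers, y_perm, alpha))
    counts_arr = np.array(counts)
    return OverlapPermutationResult(
        alpha=alpha,
        n_selected=len(selected),
        observed_joint=observed,
        permuted_counts=tuple(int(c) for c in counts_arr),
        empirical_p=float((counts_arr >= observed).mean()),
        n_perm=n_perm,
        seed=seed,
    )


#: cohort-B case subsets used for the replication grid
SUBSETS = ("all", "de_novo", "inherited")


def subset_cohort_b(
    cnvs_b: Sequence[CnvRecord], subset: str
) -> list[CnvRecord]:
    """B case CNVs of the given inheritance class, versus ALL B controls."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    out = []
    for c in cnvs_b:
        if c.label is Label.CONTROL:
            out.append(c)
        elif subset == "all":
            out.append(c)
        elif subset == "de_novo" and c.inheritance is Inheritance.DE_NOVO:
            out.append(c)
        elif subset == "inherited" and c.inheritance is Inheritance.INHERITED:
            out.append(c)
    return out


@dataclass
class Table1Cell:
    subset: str
    alpha: float
    joint_count: int | None
    empirical_p: float | None
    formatted_p: str
    degenerate: bool = False


def run_table1_grid(
    results_a: Sequence[EnrichmentResult],
    cnvs_b: Sequence[CnvRecord],
    index_b: HitIndex,
    db: PathwayDB,
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
    n_perm: int = 1000,
    seed: int = 0,
    subsets: Sequence[str] = SUBSETS,
) -> list[Table1Cell]:
    """Replication grid: subsets of B's case CNVs x selection thresholds.

    Each cell holds the number of A-selected pathways also enriched in the
    B subset at the same alpha, with its permutation p. Cells where the
    subset has no case CNVs, or where no pathway is selected, are flagged
    degenerate rather than computed.
    """
    cells: list[Table1Cell] = []
    child_seeds = iter(
        s.generate_state(1)[0] % (2**31)
        for s in np.random.SeedSequence(seed).spawn(len(subsets) * len(alphas))
    )
    for subset in subsets:
        sub_cnvs = subset_cohort_b(cnvs_b, subset)
        has_cases = any(c.label is Label.CASE for c in sub_cnvs)
        for alpha in alphas:
            cell_seed = int(next(child_seeds))
            selected = select_enriched(results_a, alpha)
            if not selected or not has_cases:
                cells.append(
                    Table1Cell(subset, alpha, None, None, "NA", degenerate=True)
                )
                continue
            res = permutation_overlap_test(
                sub_cnvs, index_b, db, selected, alpha, n_perm=n_perm, seed=cell_seed
            )
            cells.append(
                Table1Cell(
                    subset,
                    alpha,
                    res.observed_joint,
                    res.empirical_p,
                    res.formatted_p(),
                )
            )
    return cells


def format_table1(cells: Sequence[Table1Cell]) -> str:
    """Human-readable grid mirroring the replication table layout."""
    alphas = sorted({c.alpha for c in cells}, reverse=True)
    header = "CNV subset (B)" + "".join(
        f"\tN(p<{a:g})\tp" for a in alphas
    )
    lines = [header]
    for subset in dict.fromkeys(c.subset for c in cells):
        row = [subset]
        for a in alphas:
            cell = next(c for c in cells if c.subset == subset and c.alpha == a)
            row.append("NA" if cell.joint_count is None else str(cell.joint_count))
            row.append(cell.formatted_p)
        lines.append("\t".join(row))
    return "\n".join(lines)
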