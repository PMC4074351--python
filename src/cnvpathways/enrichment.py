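"""Pathway and gene enrichment via one-sided logistic deviance tests.

For each pathway, two nested binomial-logit models are fitted over the CNVs
of a cohort (or of both cohorts in the combined analysis):

    full:  case/control ~ CNV length + genes hit outside pathway + pathway hit (0/1)
    null:  case/control ~ CNV length + genes hit outside pathway

(plus a two-level cohort factor in the combined analysis). The drop in
deviance between the two fits is referred to a chi-square with 1 df and
signed by the pathway-hit coefficient to give a one-sided enrichment
p-value:

    p = 1/2 P(chi2_1 > D)      if beta_hit > 0
    p = 1 - 1/2 P(chi2_1 > D)  otherwise

which is identical to the one-sided normal tail of the signed root
sign(beta)*sqrt(D). Complete separation (common with rare CNV hits) is
handled by refitting both models with Firth's penalized likelihood and
comparing penalized likelihoods; such results carry method="penalized".

CNV length is entered in kilobases purely to condition the optimizer; the
deviance is invariant to affine rescaling of covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .logistic import fit_firth, fit_logistic, fit_mle
from .types import CnvRecord, DesignRow, GeneInterval, Label, PathwayDB
from .hits import HitIndex


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    n_case_hits: int
    n_control_hits: int
    coefficient: float  # pathway_hit term (0 when degenerate)
    deviance_drop: float
    p_one_sided: float
    converged: bool
    method: str  # "mle", "penalized" or "degenerate"
    cohort_coefficient: float | None = None  # combined analysis only

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


class DevianceTester:
    """Nested-model deviance test with a fixed design, reusable across
    outcome vectors (the permutation loop refits with permuted labels only).
    """

    def __init__(
        self,
        length_kb: np.ndarray,
        genes_outside: np.ndarray,
        pathway_hit: np.ndarray,
        cohort_b: np.ndarray | None = None,
    ) -> None:
        n = len(length_kb)
        cols = [np.ones(n), np.asarray(length_kb, float), np.asarray(genes_outside, float)]
        if cohort_b is not None:
            cols.append(np.asarray(cohort_b, float))
        # zero-variance covariates are collinear with the intercept; drop them
        covs = [cols[0]] + [c for c in cols[1:] if np.ptp(c) > 0]
        self.X_null = np.column_stack(covs)
        self.hit = np.asarray(pathway_hit, float)
        self.degenerate = bool(np.ptp(self.hit) == 0)
        if not self.degenerate:
            self.X_full = np.column_stack(covs + [self.hit])
        self._cohort_idx: int | None = None
        if cohort_b is not None:
            for i, c in enumerate(covs):
                if c is cols[3]:
                    self._cohort_idx = i

    def test(self, y: np.ndarray) -> tuple[float, float, float, bool, str, float | None]:
        """Return (coefficient, deviance_drop, p_one_sided, converged,
        method, cohort_coefficient) for outcome vector ``y``."""
        if self.degenerate:
            return 0.0, 0.0, 1.0, True, "degenerate", None
        y = np.asarray(y, float)
        full = fit_mle(self.X_full, y)
        null = fit_mle(self.X_null, y)
        if full.separated or null.separated or not (full.converged and null.converged):
            full = fit_firth(self.X_full, y)
            null = fit_firth(self.X_null, y)
            method = "penalized"
        else:
            method = "mle"
        dev = max(0.0, 2.0 * (full.loglik - null.loglik))
        coef = float(full.beta[-1])
        tail = float(stats.chi2.sf(dev, 1))
        p = 0.5 * tail if coef > 0 else 1.0 - 0.5 * tail
        cohort_coef = (
            float(full.beta[self._cohort_idx]) if self._cohort_idx is not None else None
        )
        return coef, dev, p, full.converged and null.converged, method, cohort_coef


def _tester_from_rows(
    rows: Sequence[DesignRow], include_cohort: bool
) -> tuple[DevianceTester, np.ndarray, np.ndarray]:
    rows = sorted(rows, key=lambda r: r.cnv_id)
    y = np.array([r.label for r in rows], float)
    length_kb = np.array([r.cnv_length for r in rows], float) / 1000.0
    outside = np.array([r.genes_outside for r in rows], float)
    hit = np.array([r.pathway_hit for r in rows], float)
    cohort = (
        np.array([1.0 if r.cohort == "B" else 0.0 for r in rows])
        if include_cohort
        else None
    )
    return DevianceTester(length_kb, outside, hit, cohort), y, hit


def deviance_test(
    rows: Sequence[DesignRow],
    include_cohort: bool = False,
    pathway_id: str = "",
) -> EnrichmentResult:
    """One-sided deviance test of case enrichment for one pathway."""
    labels = {r.label for r in rows}
    if labels != {0, 1}:
        raise ValueError("need at least one case and one control CNV")
    tester, y, hit = _tester_from_rows(rows, include_cohort)
    coef, dev, p, converged, method, cohort_coef = tester.test(y)
    return EnrichmentResult(
        pathway_id=pathway_id,
        n_case_hits=int(((y == 1) & (hit == 1)).sum()),
        n_control_hits=int(((y == 0) & (hit == 1)).sum()),
        coefficient=coef,
        deviance_drop=dev,
        p_one_sided=p,
        converged=converged,
        method=method,
        cohort_coefficient=cohort_coef,
    )


class PathwaySweep:
    """Shared per-CNV state for testing many pathways over one CNV set.

    Precomputes total genes hit per CNV and the gene -> CNV-row incidence,
    so each pathway only needs a bincount to get its design columns.
    """

    def __init__(
        self,
        cnvs: Sequence[CnvRecord],
        index: HitIndex,
        include_cohort: bool = False,
    ) -> None:
        self.cnvs = sorted(cnvs, key=lambda c: c.cnv_id)
        self.n = len(self.cnvs)
        self.y = np.array(
            [1.0 if c.label is Label.CASE else 0.0 for c in self.cnvs]
        )
        self.length_kb = np.array([c.length for c in self.cnvs], float) / 1000.0
        self.total_hits = np.array(
            [len(index.genes_hit(c.cnv_id)) for c in self.cnvs], float
        )
        self.cohort_b = (
            np.array([1.0 if c.cohort == "B" else 0.0 for c in self.cnvs])
            if include_cohort
            else None
        )
        row_of = {c.cnv_id: i for i, c in enumerate(self.cnvs)}
        self.gene_rows: dict[str, np.ndarray] = {
            g: np.array(sorted(row_of[c] for c in cnv_ids if c in row_of), dtype=int)
            for g, cnv_ids in index.gene_to_cnvs.items()
        }

    def in_pathway_counts(self, genes: Iterable[str]) -> np.ndarray:
        counts = np.zeros(self.n)
        for g in genes:
            rows = self.gene_rows.get(g)
            if rows is not None and len(rows):
                counts[rows] += 1.0
        return counts

    def tester(self, genes: Iterable[str]) -> tuple[DevianceTester, np.ndarray]:
        """DevianceTester for one pathway plus its binary hit vector."""
        in_pw = self.in_pathway_counts(genes)
        hit = (in_pw > 0).astype(float)
        tester = DevianceTester(
            self.length_kb, self.total_hits - in_pw, hit, self.cohort_b
        )
        return tester, hit

    def test_pathway(self, pathway_id: str, genes: Iterable[str]) -> EnrichmentResult:
        tester, hit = self.tester(genes)
        coef, dev, p, converged, method, cohort_coef = tester.test(self.y)
        return EnrichmentResult(
            pathway_id=pathway_id,
            n_case_hits=int(((self.y == 1) & (hit == 1)).sum()),
            n_control_hits=int(((self.y == 0) & (hit == 1)).sum()),
            coefficient=coef,
            deviance_drop=dev,
            p_one_sided=p,
            converged=converged,
            method=method,
            cohort_coefficient=cohort_coef,
        )


def test_all_pathways(
    cnvs: Sequence[CnvRecord],
    index: HitIndex,
    db: PathwayDB,
    include_cohort: bool = False,
) -> list[EnrichmentResult]:
    """Deviance test for every pathway, in deterministic pathway_id order.

    Degenerate pathways (hit column constant) yield p=1 results rather than
    being dropped, so the pathway universe is stable across permutation
    replicates.
    """
    sweep = PathwaySweep(cnvs, index, include_cohort)
    return [sweep.test_pathway(pid, db.genes(pid)) for pid in db]


def test_single_genes(
    cnvs: Sequence[CnvRecord],
    index: HitIndex,
    genes: Iterable[GeneInterval],
    include_cohort: bool = False,
) -> list[EnrichmentResult]:
    """Gene-specific enrichment: each gene treated as a singleton pathway."""
    db = PathwayDB()
    for g in sorted(genes):
        db.add(g.gene_id, {g.gene_id}, source="single-gene")
    return test_all_pathways(cnvs, index, db, include_cohort)


def bonferroni_threshold(alpha: float, n_pathways: int) -> float:
    """Family-wise threshold alpha / n_pathways."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    return alpha / n_pathways


def significant_genes_in_pathway(
    pathway_genes: Iterable[str],
    gene_results: Sequence[EnrichmentResult],
    alpha: float = 0.05,
) -> list[str]:
    """Pathway member genes individually enriched at p < alpha, by p."""
    genes = set(pathway_genes)
    hits = [
        r for r in gene_results if r.pathway_id in genes and r.p_one_sided < alpha
    ]
    return [r.pathway_id for r in sorted(hits, key=lambda r: (r.p_one_sided, r.pathway_id))]


def count_deviance_test(
    rows: Sequence[DesignRow],
    in_pathway_counts: Sequence[int],
    include_cohort: bool = False,
    pathway_id: str = "",
) -> EnrichmentResult:
    """Naive comparator: covariate-free genes-in-pathway COUNT test.

    Tests case/control ~ number of pathway genes hit, with none of the main
    test's covariates. Any case/control difference in CNV size or overall
    gene load then leaks straight into the count term — and for pathways
    whose genes sit physically close together a single large case CNV can
    contribute a double-digit count, so the leak is amplified exactly where
    the main test's binary indicator caps it at 1. This function exists to
    demonstrate that design choice, not for analysis.
    """
    rows = sorted(rows, key=lambda r: r.cnv_id)
    y = np.array([r.label for r in rows], float)
    counts = np.asarray(in_pathway_counts, float)
    cohort = (
        np.array([1.0 if r.cohort == "B" else 0.0 for r in rows])
        if include_cohort
        else None
    )
    n = len(rows)
    tester = DevianceTester(np.zeros(n), np.zeros(n), counts, cohort)
    coef, dev, p, converged, method, cohort_coef = tester.test(y)
    hit = counts > 0
    return EnrichmentResult(
        pathway_id=pathway_id,
        n_case_hits=int(((y == 1) & hit).sum()),
        n_control_hits=int(((y == 0) & hit).sum()),
        coefficient=coef,
        deviance_drop=dev,
        p_one_sided=p,
        converged=converged,
        method=method,
        cohort_coefficient=cohort_coef,
    )
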