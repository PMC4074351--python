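# Methods

## The statistical problem

Large (>500 kb), rare (<1% carrier frequency) copy-number variants are
strongly associated with neurodevelopmental disorders. Given CNV calls
from two case/control studies of different disorders, the questions this
package answers are:

1. per pathway (a named gene set), are case CNVs enriched for hits on the
   pathway's genes relative to control CNVs, beyond what CNV size and
   overall gene content explain?
2. do the pathways enriched in one disorder overlap the pathways enriched
   in the other more than chance predicts?
3. is any such overlap explained merely by case CNVs of the two disorders
   falling on the same genomic loci?

## The enrichment model

The unit of analysis is the CNV, labelled case (1) or control (0). A CNV
*hits* a gene when any part of it lies within the gene's
longest-transcript span (closed 1-based intervals, >=1 bp overlap). For a
pathway *P* the two nested binomial-logit models are

    full:  label ~ 1 + length + genes_outside + hit_P
    null:  label ~ 1 + length + genes_outside

where `length` is the CNV length (entered in kb — a pure conditioning
choice; the deviance is invariant to affine covariate rescaling, which the
suite checks to 1e-8), `genes_outside` the number of genes the CNV hits
that are not in *P*, and `hit_P` the 0/1 indicator of hitting >=1 gene of
*P*. The test statistic is the deviance drop D between the fits; the
one-sided enrichment p is

    p = 1/2 P(chi2_1 > D)        if the hit_P coefficient is positive,
    p = 1 - 1/2 P(chi2_1 > D)    otherwise.

This equals the one-sided normal tail of the signed root
`sign(beta)*sqrt(D)` — the two common conventions for one-sided
likelihood-ratio tests coincide, so no option is exposed. Swapping all
labels maps p to 1-p exactly.

Rationale for the design, in brief: `length` absorbs the tendency of long
CNVs to hit any gene set and of case CNVs to run large; `genes_outside`
absorbs case/control differences in overall gene load; the *binary* hit
indicator (rather than the number of pathway genes hit) caps the influence
of a single CNV striking a physical cluster of pathway genes. The
`count_deviance_test` comparator — a covariate-free count-based variant —
is included only to demonstrate what that design prevents (see the
clustered-null study below).

Gene-level tests reuse the machinery with each gene as a singleton
pathway. The combined two-cohort analysis adds a 2-level cohort factor to
both models, absorbing between-study differences in calling and ancestry.
Multiple testing uses Bonferroni over the tested pathways (no FDR).

### Separation and degeneracy

Rare-variant hit columns often separate the outcome perfectly; the
Newton-Raphson MLE then diverges. Fits that fail to converge or run past
|beta| = 30 are refitted with Firth's bias-reduced (Jeffreys-prior
penalized) likelihood, both models penalized alike, and flagged
`method="penalized"`. For a 2x2 layout this happens exactly when a margin
cell is empty. Pathways whose hit column is constant (typically all-zero)
return p = 1 flagged `degenerate` rather than being dropped, so the
pathway universe is identical in every permutation replicate. The solver
is a small dedicated Newton/Firth implementation (the permutation
machinery needs ~1e4-1e5 refits per run); it is validated against
statsmodels GLM and against direct two-binomial likelihood maximization on
an exhaustive grid of small 2x2 tables.

## Cross-disorder overlap test

Pathways with p < alpha in cohort A (alpha in {.05, .01, .001}) are
re-tested in cohort B; the statistic is the count jointly below alpha. Its
null distribution comes from permuting B's case/control labels over B's
CNVs (label totals preserved, full refit of every selected pathway per
replicate — no nuisance-coefficient reuse). The empirical p is the plain
proportion of replicates with a count at least as large as observed; a
zero numerator is displayed as "<1/n_perm" while the raw 0 stays in
machine-readable output. Labels are permuted at the CNV level, not the
individual level: individuals are not linked across CNVs in typical public
CNV lists, and rare large CNVs are nearly one-per-carrier. Replicate
streams are spawned from one master seed, so any single replicate is
reproducible in isolation. Inheritance subsets (de novo / inherited /
all B cases, each against all B controls) fill the replication grid.

## Physical-overlap regression

For direction X-vs-Y, each CNV of cohort X gets a 0/1 flag for >=1 bp
same-chromosome overlap with any *case* CNV of cohort Y (type-agnostic),
and the model `flag ~ label + length` is fitted over X with the same
signed one-sided convention. The two directions are deliberately separate
fits, not one symmetric statistic. Region exclusion for this test removes
whole CNVs touching any of the 14 built-in susceptibility loci (printed in
Mb and scaled by exactly 1e6; the one point locus becomes a 1-bp
interval), unlike the pathway reruns, which remove *genes* in those loci
and then re-derive pathway membership and hit counts.

## Filters

* CNV length: strictly greater than 500 kb.
* Frequency: CNVs single-linkage clustered at >=50% reciprocal overlap; a
  cluster is removed when its distinct-carrier count reaches 1% of the
  cohort's total sample count (supplied by the caller). The clustering
  convention is ours — how per-CNV frequency is assessed is usually left
  unstated — and both thresholds are configurable.
* Pathways: 3 to 1,500 genes inclusive, and at least 10 CNV hits in the
  combined case+control sample, counting a CNV once per pathway no matter
  how many of its genes it hits. Hit counts are recomputed after any gene
  or CNV removal.
* Boundary conventions (">" strict for length, inclusive for the pathway
  bounds and hit floor) are fixed in code and tested, since prose
  statements of such rules are habitually ambiguous.

## Synthetic study generator

The generator produces a genome (disjoint gene spans per chromosome), a
pathway database, and two cohorts' case/control CNV tables. Defaults
define the reference study conditions:

| parameter | default | why |
| --- | --- | --- |
| genome | 4 chromosomes x 75 Mb | scaled-down genome keeping per-pathway hit counts in the >=10-hit regime the pathway filter targets |
| genes | 4,000, mean span 15 kb | ~13 genes/Mb, so a ~0.8 Mb CNV hits ~10 genes |
| pathways | 200 disjoint sets of 20 genes | disjointness makes calibration rates interpretable |
| CNV counts | A: 85 case / 78 control; B: 133 case / 215 control | two-study scale matching the motivating design |
| CNV length | log-normal, median 700 kb, sigma 0.4, truncated >500 kb | right-skewed spread of large CNVs |
| del:dup | 1:3 | duplications preponderate in such data |
| de novo fraction (B cases) | 10% | exercises the inheritance subsets |

One CNV per synthetic carrier; sample counts equal CNV counts.

Signals and confounders are planted as follows.

* **Pathway enrichment** re-anchors a case CNV (with the probability that
  makes the case hit rate `boost` times baseline) onto a random gene of
  the target pathway. Re-anchoring moves a CNV without changing its
  length, so the planted effect is purely positional.
* **Shared loci**: with rate 0.4 (over 5 anchor loci) in the
  `planted_shared` preset, case CNVs of *both* cohorts are drawn to
  overlap common anchors — concentrated cross-cohort sharing that drives
  both the joint-enrichment count and the physical-overlap regression.
  The rate is a design choice: it makes sharing strong enough to dominate
  the between-pathway correlation of the permutation null at the default
  cohort sizes.
* **Clustered pathways** sample their genes from a contiguous stretch of
  `cluster_window_genes` (default 100) consecutive genes, emulating gene
  families in one neighbourhood: one CNV can hit many pathway genes at
  once, and the number it hits grows with its length.
* **Length confounding** (`case_length_tilt`): case lengths are drawn
  from the control law exponentially tilted by `exp(tilt * length_Mb)`
  (self-normalized over a 64-candidate batch). The tilt makes the true
  case/control log-odds exactly linear in CNV length — precisely the
  confound the model's length covariate absorbs — so the covariate-
  adjusted binary test is asymptotically nominal under it while models
  omitting length are genuinely misspecified.

Presets: `null` (no signal), `planted_shared` (one pathway boosted 8x in
both cohorts + shared loci), `planted_disjoint` (different pathways
boosted per cohort, no shared loci), `clustered_null` (half the pathways
clustered, case length tilt 2/Mb, *no* pathway enrichment — the
false-positive control the binary-hit design targets).

What the generator does not emulate: real CNV hotspot maps and
segmental-duplication breakpoints, array noise and calling error,
recurrent-locus allelic series, linkage between CNVs of one individual,
and real pathway databases' heavy gene-sharing and nesting. Calibration
and power results transfer to real data only qualitatively.

## Verification studies and problem sizes

The statistical suite runs these studies (all seeded, replicate counts
fixed as design choices balancing Monte-Carlo precision against runtime):

* **2x2 oracle**: on every interior 2x2 table with group sizes <= 12, the
  covariate-free deviance equals direct two-binomial likelihood
  maximization to 1e-8 (boundary tables go penalized by contract and are
  checked for that instead).
* **Type-I calibration**: null preset, 2,000 label permutations cycling
  over the 200 pathways; rejection at .05 must sit within the 99%
  binomial band 0.050 +/- 0.0126.
* **Permutation-null calibration**: 100 null meta-replicates, n_perm=200;
  the cross-disorder test must reject at <= .05 up to one-sided
  Monte-Carlo error. (Its empirical p is super-uniform: joint counts are
  small integers, so the discrete null piles mass at p = 1.)
* **Power**: 100 `planted_shared` replicates; the planted pathway must
  rank first in the combined sweep in >80%, and the joint count must
  exceed all 200 permuted counts in a majority.
* **Design contrast**: 300 `clustered_null` replicates x 20 clustered
  pathways on the combined sample; the binary-hit test must hold its .05
  level (99% z-band) while the count comparator rejects significantly
  more often (paired one-sided z at 99%). Observed rates in development
  were ~0.05 vs ~0.11.
* **Interval oracle**: hit index and overlap flags against an exhaustive
  pairwise scan on 1e4-pair random instances, 100% concordance.

`scripts/acceptance.py` re-runs the same studies (at 60-120 replicates)
from a single command-line seed and writes the measured rates as JSON.

## Known limitations

* Chi-square p-values lean on asymptotics; with fewer than ~5 hits per
  pathway the one-sided halved-LRT is conservative and discrete. The
  >=10-hit filter exists to keep tests out of that regime.
* The Firth-refit deviance compares penalized likelihoods of nested
  models, a standard but not exact-small-sample procedure.
* The frequency filter's reciprocal-overlap clustering is a convention;
  locus-based definitions would differ at the margins.
* Permuting labels at the CNV level ignores within-carrier correlation;
  with approximately one large rare CNV per carrier this is benign, but
  multi-CNV carriers would need individual-level permutation.
* The cross-overlap survivor counts of the motivating study's published
  case lists (55 and 102) cannot be checked without those supplementary
  files; the corresponding test requires a locally supplied copy.
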