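# Methods

This note documents the models implemented in `funbat`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Expression specificity profiles

For a cell×gene count matrix with cells grouped into clusters (cell type ×
developmental epoch; clusters under 50 cells are excluded as unstable), a
gene's **sensitivity** for a cluster is the fraction of in-cluster cells with
raw read count ≥ 1, and its **specificity** is the fraction of
out-of-cluster cells with count 0. Sweeping the detection threshold over all
observed counts traces a ROC curve; its area (**AUC**) is computed as the
normalized Mann–Whitney statistic — the probability that a random in-cluster
cell has a higher count than a random out-of-cluster cell, ties counted half,
which is exactly the trapezoidal area under the threshold-sweep ROC. A gene
expressed identically in all cells scores exactly 0.5; all-zero genes are
all-ties, score 0.5, and have sensitivity_max = 0, so the low-detection
filter (drop genes with sensitivity_max < 10%) removes them without special
cases. AUC is computed on raw counts; the log-CPM layer
(`log(1 + 1e6·count/cell_total)`, natural log — the base is a convention and
only rescales scores) is used for assignment scores and PCA validation.

## Assignment scores and gene sets

Let `x_i` be a gene's mean log-CPM in cluster `i`:

* **z-score**: `(x_i − μ)/σ` with μ, σ the mean and *population* SD of the
  gene's per-cluster means. The population/sample choice only rescales each
  gene's scores by a common factor and cannot change within-gene rankings;
  across-gene top-N ranking is also unaffected at fixed cluster count.
  σ = 0 (constant genes) scores 0 everywhere, flagged.
* **EP**: `x_i / Σ_j x_j`; rows sum to 1; all-zero genes are excluded.
* **EE**: EP divided by the cluster's share of total expression
  `s_i / Σ_j s_j` (with `s_i` the summed mean expression of cluster i), so a
  uniformly expressed gene scores 1 everywhere and the weighted sum
  `Σ_i (s_i/Σs)·EE_i` is identically 1. If the intended placement of the sum
  in the conventional formula differs, the alternative differs only by a
  per-cluster constant and leaves within-cluster rankings unchanged.
* **Wilcoxon**: tie-corrected rank-sum z of in-cluster vs out-of-cluster
  per-cell expression. The z statistic (not a signed p-value) is used for
  ranking; the two are monotone-equivalent one-sided.

Fixed-size sets (default 600 genes per cluster; our synthetic defaults use
100 = 5 × markers-per-cluster) are the top-N genes per cluster after the
low-detection filter, ties broken by (score desc, gene id asc) for
reproducibility. The genetic-constraint filter removes genes with
LOEUF > 0.6 *after* the top-N selection, so constrained sets may be smaller
than N; genes lacking a LOEUF annotation are treated as unconstrained
(removed, counted in the metadata). Validation projects cells onto PC1 of a
100-gene specificity window (log-CPM, centered per gene, unscaled; the
projection is computed as an explicit dot product with the component so that
identical cells tie exactly) and reports the in/out AUC oriented ≥ 0.5.

## Variant QC and collapsing

Short-variant QC is a conjunction of per-record predicates (hence
order-invariant): DP ≥ 20, GQ ≥ 30, allele ratio ∈ [0.2, 0.8], cohort and
reference allele frequency ≤ 1e-3 (the "rarer than 1/1,000" rule is applied
as an allele-frequency threshold, the gnomAD convention), and per class:
LoFtee high-confidence for stop-gained/frameshift, AlphaMissense ≥ 0.9 for
missense, SpliceAI max delta ≥ 0.8 for splice, nothing extra for synonymous.
Records of a score-gated class with the score missing are dropped and counted
separately. CNVs need likelihood score ≥ 30 and size ≥ 50 kb; copy number
< 2 is a deletion, > 2 a duplication, exactly 2 is dropped as a non-CNV.
Batch harmonization tests each distinct CNV's parent carrier frequency
across batches by chi-square and removes BH-significant heterogeneity.

CNV–gene intersection uses 0-based half-open intervals and counts any ≥ 1 bp
overlap as disruption (the minimum-coverage fraction is configurable in
principle but not enforced by default). Collapsing maps QC-passing variants
to binary (individual, gene, class) flags — idempotent and monotone by
construction.

De novo calling requires both parents present and no read evidence of the
variant in either parent; one variant per (offspring, gene) is kept by
consequence severity (stop_gained > frameshift > splice > missense >
synonymous, the standard effect ranking); offspring with > 10 genes carrying
a de novo synonymous variant are removed as likely sample-quality outliers.
The synonymous-gene count is taken before the per-gene severity selection,
so a gene with both a synonymous and a more severe de novo still counts
toward the outlier rule.

## The burden association model

An individual's burden for a gene set and class is the number of distinct
set genes with a disruption flag. The association with affection status is
estimated by **conditional logistic regression** with the family as stratum:

    logit P(affected) = α_family + β1·burden + sex + PC1..PC10 + n_synonymous

The likelihood conditions each family on its number of cases, eliminating
α_family and with it shared-environment and relatedness confounding.
Families of one individual, or without both outcomes, carry no information
and are dropped (counted). Covariates constant within every informative
stratum are unidentifiable; they are accepted in the formula for fidelity
but reported as NaN. `n_synonymous` counts QC-passing synonymous variant
*calls* per individual (not disrupted genes).

The solver enumerates the within-stratum case subsets exactly (families are
small; the subset count is capped defensively) and maximizes by
Newton–Raphson with step halving, gradient tolerance 1e-8 and an iteration
cap. Complete or quasi-complete separation is reported with a `diverged`
flag rather than silently capped; a penalized fallback is deliberately not
applied by default. Wald tests are used for inference; in small or sparse
cohorts they are mildly anti-conservative, which the type-I simulations
quantify (empirical level ≈ 0.05–0.065 at 500 families).

For multigenic CNV classes (deletion/duplication) two genome-background
burdens are added — constrained (LOEUF < 1) and unconstrained (LOEUF ≥ 1)
genes outside the studied set — to absorb the cumulative effect of the other
genes a CNV spans. The foreground constraint filter (0.6) and the background
split (1.0) are deliberately distinct cutoffs, both exposed. Short-variant
classes use the single-burden model; the two-burden design can be forced on
or off per call.

BH FDR is applied over the declared family of tests — by default all
(gene set × class) cells of one scan, configurable to per-class families.
Cohort-downsampling stability resamples families without replacement at
10%–90% (20 replicates each by default) and reports the Spearman correlation
of each replicate's estimate vector against the full-cohort vector.

## Post-hoc analyses

* **Prioritization**: 1,000 random 100-gene subsets of a set are each
  burden-tested; subsets are called significant by BH over the subset family;
  each gene then gets a two-sided Fisher exact test on (subset significant?)
  × (subset contains gene?) — the 2×2 conditions on the realized membership
  counts — with a second, separate BH family over genes. Prioritized:
  q < 0.05 and OR > 1.
* **Enrichment**: two-sided Fisher exact over a declared reference universe;
  the sample OR uses the Haldane 0.5 correction when a cell is zero
  (flagged).
* **De novo enrichment**: (de novo, inherited) × (in set, all expressed
  genes), or per set (de novo, inherited) × (case, unaffected sibling);
  BH across sets.
* **Effect-size normalization**: burden estimates shrink as sets grow, so
  estimates are z-normalized against random gene sets drawn on a size grid
  (50..950 step 50, 30 per size by default); the closest grid size is used,
  ties to the smaller size; SD = 0 yields NA.
* **Subgroup bias**: the observed statistic is the difference of β1 between
  the two case subgroups (difference of log-OR, chosen over OR for
  symmetry), each estimated after dropping the other subgroup's cases while
  sharing all controls. The null permutes case subgroup labels only, at the
  observed proportion. Significance follows the [5th, 95th] percentile band
  of the permutation distribution; a symmetric two-tailed empirical p
  (`2·min(tails+1)/(n+1)`) is reported alongside and BH-corrected.

## Synthetic data

The expression generator draws negative-binomial counts (gamma–Poisson,
dispersion 0.5) with baseline mean 0.5 per gene per cell, Bernoulli dropout
(default 0.3), and markers whose mean is fold-elevated (default 8×) in their
home cluster; defaults are 3 cell types × 2 epochs × 200 cells and 1,000
genes with 20 markers per cluster — a desk-scale analogue of a cortical
snRNA-seq atlas's 18 types × 6 epochs structure. It does not emulate
library-size variation across cell types, correlated gene programs,
batch/donor effects, or ambient RNA; marker recovery and window-AUC results
on it therefore show correctness of the scoring machinery, not performance
on real tissue.

The cohort generator builds trio/quad/singleton families (default mix
0.4/0.3/0.2, plus 0.1 all-affected families to exercise strata filtering).
Founders receive variant *sites* per gene per class at Poisson rates
(defaults per gene per founder: 1e-3 stop-gained, 1e-3 frameshift, 5e-4
splice, 5e-3 missense, 1e-2 synonymous, 2e-4 deletions/duplications);
each parental site is transmitted to each offspring independently with
probability 1/2 (parents assort independently), and de novo sites are
injected into offspring at 10% of the class rate. Site-level annotations
(frequencies, LoFtee/AlphaMissense/SpliceAI) are shared by carriers of a
site; call-level QC fields (DP, GQ, allele ratio) are drawn per call, with
configurable failure fractions (defaults 5–10%) so the filters have work to
do. Parental-carrier flags are computed from the actual parental site sets,
making de novo truth exactly "absent from both parents".

Affection status is drawn from a logistic liability on the *post-QC* burden
of the planted gene sets, with the intercept bisected to hit the target
offspring case fraction (default 0.5, a case/sibling-like design). Parents
are drawn from the same model as offspring: family members are exchangeable,
the conditional likelihood is correctly specified, and planted log-odds
ratios are recoverable — the cost is that parental prevalence is unrealistic,
which is irrelevant to the estimator being tested. Linkage, haplotypes,
population structure (PCs are pure noise columns) and assortative mating are
not modeled.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` size their simulations for a
single CPU: null calibration uses 500-family cohorts over a 300-gene
universe (1,000 replicates in the suite, 600 in the script), parameter
recovery uses 2,000 families (200 and 100 replicates respectively), and
driver prioritization uses 2,500 families with a 400-gene universe, a
300-gene set containing 10 drivers (missense rate 0.02/gene, planted
log-OR 6 per disrupted driver gene — a deliberately syndromic-scale effect
so that subset significance tracks driver content) and 1,000 (suite) or 500
(script) random 100-gene subsets. The empirical type-I level at these sizes
is 0.05–0.065 (Wald), mean recovered β̂1 is within two Monte-Carlo SE of the
planted 0.5, and prioritization recovers all 10 drivers with ≈1–2% false
prioritization.

## Known limitations

* The exact-enumeration solver targets family-sized strata; very large
  strata (hundreds of members) would need the recursive conditional-likelihood
  algorithm, which is not implemented.
* Wald inference only; no exact conditional or score tests, no Firth
  penalization.
* The CNV generator plants dosage events independently per individual (no
  CNV inheritance), so de novo analysis applies to short variants only.
* Segmental-duplication/HLA/centromere overlap filtering is accepted as a
  precomputed column; the genomic tracks themselves are out of scope.
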