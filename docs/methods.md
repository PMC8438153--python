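# Methods

This note documents the models, the numerical choices, and what the synthetic
cohorts do and do not establish.

## The score construction

The per-sample infiltration score is a difference of two single-sample
enrichment scores,

    ICIscore_j = ScoreA_j − ScoreB_j,

where signature A holds genes positively correlated — and B negatively
correlated — with an ordering of the expression-derived gene clusters, so the
score is oriented from immune-cold to immune-hot by construction. The cohort
is dichotomized at the median, with ties assigned to the low group so the
split is deterministic.

The "cluster signature" the correlations are taken against is not uniquely
defined by the underlying procedure. We encode it as the gene-cluster label
mapped to consecutive integers ordered by each cluster's mean immune score
(`ordinal`, the default), with a one-vs-hottest `indicator` encoding exposed
as an alternative. Only the *sign* of each gene's correlation matters
downstream, so any encoding that ranks the hottest cluster highest yields the
same A/B split for genes whose expression is monotone in immune content.

## ssGSEA

For each sample, genes are ranked by expression (descending, ties receiving
midranks, residual ties broken by stable gene order so results are
platform-independent). The enrichment score of a set S is the sum over all
list positions of the difference between the weighted in-set ECDF — weights
|rank statistic|^α normalized over S — and the uniform ECDF over out-of-set
genes. The rank statistic is the per-sample midrank, not the raw value, which
makes the score invariant to monotone unit changes (exactly so at α = 0).
Defaults: α = 0.25; matrix-wide min–max normalization is available and is off
for the ICI score itself (a shared positive divisor would not change the
ordering or the median split, but raw differences are easier to interpret and
to transfer to external cohorts). For a singleton set containing the
top-ranked of N genes at α = 0, the score has the closed form
Σᵢ (1 − (i−1)/(N−1)) = N/2; the bottom-ranked singleton gives −N/2. Both are
used as fixed-point tests, together with a naive position-by-position oracle.

## Deconvolution

Cell-type fractions are estimated per sample by linear-kernel ν-support-vector
regression of the (z-scored) sample expression on the signature-matrix
columns, over ν ∈ {0.25, 0.5, 0.75}; the fit with the smallest residual RMSE
wins, negative coefficients are clamped to zero and the remainder normalized
to sum to one. Signature columns are standardized per column (coefficients are
un-scaled afterwards); this conditions the QP well. Deconvolution operates on
the linear scale — log2 input is anti-logged first — and, as in curated
references, on the signature's discriminative marker rows
(`select_signature_genes`, default top 150 by across-type contrast): basal
housekeeping rows add no identification and slow the solver. Samples whose
coefficients are all non-positive are flagged (NaN fractions), never silently
zero-filled. A non-negative least-squares solver is available behind
`method="nnls"`.

Relative mode only, and no permutation-based significance filter: the
downstream clustering consumes every sample's fractions regardless of fit
quality, with fit diagnostics (residual RMSE, correlation, chosen ν) reported
alongside.

## Batch correction

The parametric empirical-Bayes location/scale model: per-gene standardization
against a batch-size-weighted grand mean and pooled variance; per-batch
per-gene location (γ) and scale (δ) estimates; γ shrunk toward a normal prior
and δ toward an inverse-gamma prior with moment-matched hyperparameters; the
two conditional posterior means iterated to relative change < 1e-6 (cap 100
iterations — typically < 30 on all fixtures); back-transformation. Correction
is applied on the log2 scale. A single batch is an explicit identity. No
covariates are modeled, and there is no reference-batch or non-parametric
mode.

## Consensus clustering

For each candidate k, `reps` subsamples of ⌈0.9·n⌉ samples are clustered and
the consensus matrix accumulates co-clustering rates among co-sampled pairs.
Pairs never co-sampled are kept as missing (not zero) and imputed with the
mean observed consensus only for label extraction. The area under the CDF of
consensus values is computed as 1 − mean(consensus); the relative delta-area
is Δ(2) = A(2), Δ(k) = (A(k) − A(k−1))/A(k−1), clipped at 0. The chosen k is
the largest k with Δ(k) ≥ 0.1, falling back to argmax Δ; the threshold is a
recorded, overridable parameter. Final labels come from average-linkage
hierarchical clustering of 1 − M(k*) (PAM fallback if the cut yields fewer
than k* groups).

Base methods: PAM (deterministic BUILD initialization followed by alternating
assignment/medoid updates — determinism keeps the k-selection statistics
stable across repetitions and matches the reference implementation of PAM),
k-means (euclidean only), and average-linkage hierarchical. Distances:
euclidean, or Spearman (1 − rank correlation of sample profiles). The
infiltration-subtype run clusters the z-scored TME features (fractions +
immune + stroma scores) with PAM/euclidean; the gene-cluster run uses
PAM/Spearman on DEG expression. Defaults for cohort analysis are 1000 and 500
repetitions respectively; simulation studies in the test-suite scale these
down (see below).

## Differential expression

Per subtype, a one-vs-rest contrast with empirical-Bayes variance moderation:
the gene-wise pooled variances are shrunk toward a common prior via a
scaled-F model whose prior df d₀ and scale s₀² are moment-matched on
log-variances (trigamma inversion by Newton iteration); the moderated t has
d₀ + df degrees of freedom. Setting the prior df to 0 recovers the ordinary
two-sample t exactly, which is tested. Significance requires BH-adjusted
p < 0.05 within contrast and |log2FC| ≥ log2(1.65); the pooled DEG list is
the union over contrasts. The fold-change cutoff is interpreted on the linear
scale (|log2FC| ≥ log2(1.65)) and is a configuration parameter.

## Boruta

Each iteration appends a shuffled shadow copy of every still-active feature,
fits a random forest (mean-decrease-in-impurity importances), and counts a
hit for real features beating the best shadow. After a 5-iteration warm-up,
accumulated hits are tested against Binomial(n, ½), two-sided with BH
correction at α = 0.05: significantly many hits confirms, significantly few
rejects (rejected features leave the active set). Features still undecided at
`max_iter` are dropped — the conservative choice, since an unconfirmed gene
should not enter a frozen signature. In the pipeline the candidates are the
A/B genes ranked by |correlation| and balanced across the two signatures; if
Boruta empties one side entirely, that side falls back to its full gene list
so the score remains computable.

## Survival and genomics statistics

Kaplan–Meier estimation and the (multivariate) log-rank test are delegated to
lifelines; rank tests to scipy (Mann–Whitney with tie-corrected normal
approximation for two groups, Kruskal–Wallis otherwise; all-tied inputs
return statistic 0, p = 1 by documented convention); per-gene mutation
contrasts use the two-sided Fisher exact test — a rank test cannot produce a
per-gene 2×2 p-value, so Fisher is the implemented reading. TMB is the raw
per-sample count of retained mutation records (no per-megabase divisor is
assumed; one can be applied by the caller), defined only for samples declared
covered by sequencing — uncovered samples are excluded with a warning, never
imputed as zero. All median splits assign ties to the low group. The
stratified analysis forms the four TMB × ICI groups (3-df log-rank) plus the
ICI contrast inside each TMB stratum.

## The synthetic cohort generator

Per sample: a latent group g (default 3: hot / intermediate / cold); cell
fractions ~ Dirichlet with one dominant cell type per group plus extra weight
on the immune effector type that decays from hot to cold, so immune content
is a monotone gradient while the groups stay separable in fraction space;
linear expression = signature · fractions, plus a planted up-shift on each
group's own DE gene block, plus Gaussian noise, floored at 0 and
log2(x+1)-transformed; a per-batch per-gene Gaussian shift is then added on
the log scale (matching the additive-on-log model the batch correction
assumes). Survival is exponential with hazard = 0.02 · HR(g), HR defaults
(1.0, 1.5, 2.0) hot→cold, under independent Uniform(0, 120) censoring (event
fraction ≈ 0.6–0.8). Mutation burden is Poisson with rates (15, 10, 5)
hot→cold, echoing the positive burden–infiltration association seen in
immunogenic tumors; five designated driver genes are enriched in the hot
group so per-gene frequency contrasts have a planted truth. A
`structure_seed` separates gene-level structure (marker blocks, DE gene
identities) from sample-level draws so held-out cohorts can share structure.

What the generator does *not* emulate: real marker-gene overlap between cell
types, compositional expression distributions of any specific tumor type,
realistic mutation spectra or per-megabase calibration, informative
censoring, or probe-level microarray artifacts. Passing tests therefore show
the pipeline recovers the structure it assumes, with correct error control —
not that any particular biological cohort will separate.

## Problem sizes in tests and the acceptance script

Simulation studies run at: deconvolution 50–100 samples × 100 genes × 5 cell
types; consensus recovery n = 120 over 20 seeds at 200 repetitions; null DEG
calibration 1000 genes × 100 samples × 20 seeds; Boruta 200 × 60 over 10
seeds; and 100 full-pipeline replicates at n = 300 with consensus repetitions
40, Boruta capped at 20 iterations / 40 trees and signatures capped at 60
genes (`headline_config`). These scaled-down stage budgets are the package's
simulation-study design; the construction is identical to the cohort-scale
defaults.

## Known limitations

- The chosen-k rule (Δ ≥ 0.1) is a codified reading of the CDF/delta-area
  criterion, which in practice is often judged by eye; ambiguous geometries
  near the threshold can flip between adjacent k.
- ν-SVR solve times grow sharply when noise is small relative to the tube
  width; the marker-gene restriction keeps this manageable.
- The Boruta reduction is conservative at small iteration budgets: undecided
  genes are dropped, so very small budgets shrink signatures toward the
  strongest genes.
- `validate_external_cohort` requires ≥ 50% signature-gene overlap (both
  signatures non-empty) and reports the overlap; scores are not recalibrated
  to the new cohort beyond its own median split.
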