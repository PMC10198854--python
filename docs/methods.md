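# Methods

This note documents the statistical models, defaults and numerical choices
behind `tlsig`, and what the synthetic test-bed does and does not
demonstrate about real cohorts.

## TLS score and stratification

The TLS score is the geometric mean of the 13 signature chemokines'
linear-scale abundances, computed as the arithmetic mean of log2(v + 1)
and reported in log2 units. The +1 shift keeps zero TPMs finite and is the
common convention for TPM-scale data; the score of a sample whose signature
genes are all zero is therefore 0, not an error. The expression scale
(`linear` vs `log2p1`) is always declared by the caller and never inferred,
because cohorts mix TPM matrices with log2/RMA-normalized arrays and silent
inference is a reliable source of corruption. Missing signature genes are
tolerated down to 70% coverage (configurable), listed in the score
metadata, and warned about.

Quartiles use linear interpolation (type 7), the default of essentially
every numerical environment; the thresholds Q1/Q3 are reported with the
stratification. Two dialects are implemented because the published
two-class rule (hi = score strictly greater than Q3, low otherwise)
coexists with three-class TLS-hi/inter/low survival stratifications:
`three_class` (hi > Q3, low < Q1, inter between — the default for survival
comparisons) and `two_class_q3` (the literal rule, used for hi-vs-low
two-group comparisons). Whether the inter class should be bounded by Q1 or
the median is not determined by its source; Q1 is this package's recorded
choice. With constant scores every sample lands in the low class (hi
requires a strict inequality) and a warning is emitted.

A `check_signature_coherence` report flags signature genes whose expression
is negatively correlated with the leave-one-out signature mean — the
pruning rule that historically removed BCL6 from the candidate chemokine
list.

## Survival models

Kaplan–Meier, log-rank and Cox regression are implemented from first
principles (the test suite cross-checks them against lifelines).
Conventions: `event = 1` is death/event, times are strictly positive,
subjects censored at an event time remain at risk at that time.

* **Kaplan–Meier**: product-limit over distinct event times with Greenwood
  variance. A group without events yields a flat curve and a warning, not
  an error.
* **Log-rank**: per event time, per-group expected events are the
  hypergeometric mean and the covariance the hypergeometric variance
  (including the (n−d)/(n−1) ties factor); the k-group statistic is the
  quadratic form over the first k−1 groups against χ²(k−1).
* **Cox**: Newton–Raphson on the partial likelihood with step-halving.
  Efron tie handling is the default (ties are guaranteed in day-resolution
  data; Breslow is available for cross-checks). Convergence requires
  max|score| < 1e-9 or a matching relative log-likelihood change within 50
  iterations; non-convergence (monotone likelihood / separation) returns a
  flagged fit with a warning. Standard errors come from the inverse
  observed information; confidence intervals and p-values are Wald
  (exp(β ± 1.96·SE)). Covariates are centered internally (the partial
  likelihood is shift-invariant), constant covariates are dropped with a
  warning, and a rank-deficient design raises an error naming the collinear
  columns. The score test at β = 0 is provided separately; for a binary
  covariate with untied times it reproduces the log-rank χ² exactly.

The univariate/multivariate screen expands categorical covariates to
reference-coded indicators (reference = first level alphabetically unless
overridden) and reports BH-adjusted q alongside raw p across the
univariate fits.

## Interaction screen

For focal score F and gene expression V, the model h = a·F + b·V + d·F·V +
c is fit per gene as a three-covariate Cox regression. The intercept c is
not identifiable in a partial likelihood (it scales the baseline hazard)
and is therefore a generator-side parameter only. F and V are z-scored
before fitting so d is comparable across genes; the product is formed after
standardization. Genes with SD < 1e-8 are skipped; collinear or degenerate
fits are flagged as non-convergent and excluded from classification, never
silently classified.

Classification: a gene is an enhancer (d < 0) or reducer (d > 0) when its
raw Wald p for d passes `p_threshold` and its BH q passes `fdr_threshold`.
The default `fdr_threshold = 1.0` disables the FDR gate, matching raw-p
filtering; the calibrated preset used in the tests is p ≤ 0.05 with
FDR ≤ 0.1. The screen filters on the interaction p-value only.

Standard errors are model-based (inverse information), the convention of
every mainstream Cox implementation. Note that a per-gene three-covariate
model is a *working* marginal model: when many genes truly interact with
survival simultaneously, the omitted terms act as unobserved heterogeneity
(frailty), which attenuates marginal coefficient estimates toward zero and
inflates the dispersion of null-gene p-values. On the default synthetic
cohort — which plants 40 joint interaction effects of |d| = 0.5, a combined
log-hazard heterogeneity of SD ≈ 1.6 — measured per-gene estimates shrink
to roughly half their single-gene values and null p-values are mildly
anti-conservative (~13% below 0.05). This is a property of marginal
screening itself, not of the optimizer, and applies equally to real
cohorts: the screen ranks and classifies modulator candidates, it does not
deliver calibrated per-gene inference under dense signal. With a single
planted interaction (or none), estimates and p-values are accurate and
uniform respectively, which the test suite verifies.

## Gene-set scoring

ssGSEA per sample: genes are ranked by expression (average rank for ties)
and ordered from highest to lowest; the enrichment score is the sum over
the list of the weighted in-set cumulative distribution (weights =
rank^α, α = 0.25 by default) minus the unweighted out-of-set cumulative
distribution. The score depends only on ranks, so it is invariant under any
strictly monotone transform of a sample's expression. Min–max normalization
across samples is available but off by default because it couples samples
and breaks single-sample semantics.

Because in-set steps are rank-weighted, the statistic is *not* mean-zero
for random gene sets: the weighted in-set CDF stochastically dominates the
uniform out-of-set CDF, giving a positive null expectation of approximately
Σᵢ(Cᵢ/C_G − i/G), where Cᵢ is the cumulative rank-weight. For G = 200
genes, k = 20, α = 0.25 this is ≈ 10.9 — about 14% of the permutation-null
range — and the test suite asserts the permutation mean against this
analytic value. Field-standard implementations share the bias; it cancels
in between-sample or between-group comparisons, which is how the scores
are used here.

The marker-mean score (the arithmetic mean of log2(v + 1) over a marker
set) is the MCP-counter-style aggregate; on the 13-gene signature it equals
the TLS score exactly, which the suite checks as a cross-module identity.
Score–score correlations (Spearman default) report NaN for pairs with
fewer than 5 shared samples.

## Differential expression and enrichment

Two-group differential expression uses the Wilcoxon rank-sum test on log2
values by default (Welch t optional; moderated-t shrinkage is out of
scope). The fold change is the ratio of *linear-scale* group means (with a
1e-9 pseudocount); the published threshold |FC| > 1.5 does not state a
scale, and the linear convention is recorded in the output. A gene is
up/down only when both |log2FC| > log2(1.5) and p < 0.05 hold. Constant
genes get p = 1 by convention.

Over-representation is the hypergeometric upper tail P(X ≥ k) of the
query/set overlap within a user-supplied universe, BH-corrected across
sets. The keep rule requires at least 5 query genes in the category
(configurable) plus FDR < 0.05 in GO mode or raw p < 0.05 in pathway mode.
No annotation database is bundled — GO/KEGG universes are version-dependent
and arrive as GMTs.

## Mutations

TMB is the raw count of nonsynonymous records per sample (Missense,
Nonsense, Nonstop, Frame_Shift_Ins/Del, In_Frame_Ins/Del, Splice_Site,
Translation_Start_Site by default; configurable), with no exome-size
normalization. Duplicate (sample, gene, class) records count once; roster
samples without records count 0. Per-gene group frequencies are binary (a
sample is mutated if it has ≥ 1 nonsynonymous record for the gene) and are
compared across two groups by Fisher's exact test with BH correction.
TMB-high/low splits use the strictly-greater-than-threshold rule,
consistent with the score stratification.

## TME classification

The panel joins per-sample parameters (signature scores, TMB, any score
table) on shared samples (≥ 90% overlap required), z-scores each column,
drops constant columns with a warning, and handles missing cells by
dropping samples (default) or mean imputation. Clustering is complete-
linkage agglomeration on Euclidean distances (delegated to scipy's
deterministic nearest-neighbor-chain implementation; the merge history is
exported as child1/child2/height/size), cut to exactly k clusters (k = 5
by default, matching the published five-class HNSCC TME taxonomy; no
automatic k selection is attempted because none was described). Cluster
labels are renumbered by ascending mean TLS z-score, so label k is always
the TLS-highest class and the numbering is stable across runs. Cluster
profiles (mean z per parameter), the k-group log-rank test and per-cluster
KM curves summarize each class; planted-archetype validation matches
recovered profiles to archetype centers by Hungarian assignment on profile
correlation.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes;
it is a test-bed, not a biological simulator.

* **Expression** (log2(TPM+1) scale): per-gene baselines ~ U(2, 6) (a
  realistic log2-TPM range for expressed genes), signature genes get
  `tls_effect` · F added for a latent factor F ~ N(0, 1), all genes get
  N(0, `noise_sd`) noise, and values are clipped at 0. Defaults
  tls_effect = 1, noise_sd = 0.5, giving a per-gene gene–factor correlation
  of 1/√1.25 ≈ 0.89.
* **Survival**: exponential event times with rate exp(c + a·F + Σ b_g·V_g +
  Σ d_g·F·V_g), V centered so c is the baseline log-hazard (c = −2.5
  default, putting median survival near 10 time units at the cohort
  center); independent exponential censoring whose rate is solved by root
  finding so the expected censoring fraction hits the target (0.3 default).
  Exponential baselines make Cox coefficient recovery exact in expectation.
* **Mutations**: independent Bernoulli per (sample, gene) at group-specific
  frequencies, emitted as Missense_Mutation records. The default cohort
  plants MUC16-like (22% vs 17%) and CASP8-like (10% vs 22%) frequencies
  across TLS-hi/low plus 40 background genes at 8%.
* **Response**: cumulative-logit ordinal labels over PD < SD < PR < CR with
  baseline mix 0.40/0.30/0.18/0.12 (typical of checkpoint-blockade trials)
  shifted toward CR by `response_shift` · F.
* **Default cohort**: 600 samples, 500 genes, the 13 signature genes, 20
  interaction enhancers (d = −0.5), 20 reducers (d = +0.5), a = −0.7.
* **TME archetypes**: 5 planted classes × 50 samples over 8 z-scale
  parameters with within-class SD 0.5, following the published five-class
  profiles (immune desert / immune-low TMB-high / immune-and-stroma-rich /
  stromal immune-desert / immune-hot TLS-high); the stromal immune-desert
  class carries the largest baseline hazard and the immune-hot class the
  smallest.

One global seed expands into fixed per-stage child seeds
(`np.random.default_rng([seed, stage])`), so any stage re-run in isolation
reproduces the orchestrated run.

What passing tests on this generator do **not** show: robustness to
negative-binomial count noise, library-size and batch effects, probe-level
microarray artifacts, copy-number-driven expression, non-proportional
hazards, informative censoring, or the correlated gene–gene structure of
real transcriptomes. Effect sizes were chosen for testability (they make
planted structure recoverable at n = 600), not calibrated to any cohort.

## Problem sizes and runtime

The default suite and the acceptance script use the sizes above (600 × 500
cohort, 250-sample archetype panel, 200-gene calibration cohorts, 500
permutations for the ssGSEA null), which keep a full run on one CPU in the
low minutes while leaving planted effects several standard errors from
zero.

## Known limitations

* The Cox implementation covers fixed covariates only: no time-varying
  covariates, stratified baselines, frailty terms or PH diagnostics.
* The interaction screen's marginal p-values are anti-conservative under
  dense joint signal (see above); treat gene classes as ranked candidates.
* ssGSEA raw scores carry the positive rank-weighting offset; compare
  scores across samples or groups, not against zero.
* ORA requires a user-supplied universe and GMTs; results are only as
  current as the annotation release behind them.
* The MAF reader consumes a 3-column projection (sample, gene, class);
  variant-level detail (position, allele, VAF) is out of scope.
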