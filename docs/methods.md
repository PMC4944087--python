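# Methods

## Model and procedure

The package treats pathway-guided feature selection as a three-stage
supervised procedure on a log2-scale genes × samples matrix with binary
labels (`diseased` / `control`):

1. **Set-level testing.** Per gene, the SAM moderated statistic
   d_i = (x̄_di − x̄_ci)/(s_i + s0), where s_i is the pooled standard error
   of the two-sample mean difference, s_i = sqrt((1/n_d + 1/n_c)·SS/(n_d +
   n_c − 2)), and s0 ≥ 0 a shared damping constant. A set's statistic is
   the squared L2 norm Σ d_i² over its mapped members; its p-value comes
   from B class-size-preserving label permutations with the add-one
   convention p = (1 + #{SAMGS_b ≥ SAMGS_obs})/(1 + B), so p is never 0 and
   ties count against the observed statistic (conservative).
2. **Reduction.** Members of each set with p ≤ α are ordered by decreasing
   |d_i| (stable sort; ties keep input order). c_k is the permutation
   p-value of the complement after removing the top k; the core is the
   shortest prefix with c_k > c, and the empty complement is assigned
   c_{|j|} = 1 so termination is guaranteed. The selected panel is the
   deduplicated union of cores, ordered by decreasing |d| then gene ID.
3. **Classification.** A linear SVM (cost 1) with sigmoid (Platt)
   calibration fitted by internal cross-validation, scored by
   misclassification error, generalized Brier score (mean squared
   belief-indicator distance halved, so a confident miss scores exactly 1),
   belief confusion metric (mean belief in the true class), and AUPR for
   the diseased class by step interpolation (Σ precision·Δrecall over
   descending score thresholds; tied scores enter together, and no
   trapezoids, avoiding the optimistic bias of linear interpolation).
   The argmax rule breaks belief ties at 0.5 toward the diseased class.

Assumptions: two classes with at least two samples each (the pooled SD must
be estimable); expression already normalized onto a comparable scale
(helpers for CPM+log2 of counts and quantile normalization are provided);
gene sets meaningful for the tissue under study. The set-level test is used
as a tuning device, not an inferential claim — p-values carry no
multiplicity correction, mirroring the role of α as a sparsity knob.

## Permutation machinery

One `PermutationScheme` (B label shuffles) is drawn per fit and shared by
every set and every reduction step: per-gene permuted d² values are
computed once as a genes × B matrix, so any subset's null statistics are
column sums and the whole reduction trace of a set falls out of suffix
sums. Work scales as B × genes rather than B × sets × genes, and p-values
are comparable across sets because they share the same draws. s0 is
estimated from the observed labels and held fixed under permutation (the
gene set and s0 are part of the fixed statistic definition; a
`re-estimated` policy is available). An exact-enumeration path scores all
C(n, n_d) label assignments (observed included, so p ≥ 1/total) and serves
as a small-sample oracle for the Monte-Carlo path.

Numerical choices: observed and permuted statistics come from algebraically
equivalent but differently rounded expressions, so the ≥ comparison uses a
floor of one part in 10⁹ below the observed value — ties at machine
precision count against the observed statistic, in the conservative
direction.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| α grid | 0.01, 0.05, 0.1, 0.15, 0.2 | set-level significance cut |
| c grid | 0.01, 0.05 … 0.30 | complement threshold; larger c reduces deeper, since the rule stops at the first c_k **exceeding** c |
| B (refit / within-CV) | 1000 / 500 | within-CV budget halved as a speed–resolution trade-off; c needs resolution ≳ 1/(B+1) |
| s0 | estimated | percentiles {0,5,…,100} of s_i, minimizing the coefficient of variation of the per-scatter-bin MAD of d; forced positive if any s_i = 0 |
| CV folds | 5 | stratified, seeded, shared across all grid cells |
| min_set_size | 2 | a 1-gene set makes reduction vacuous |
| SVM kernel / C | linear / 1 | standard at p ≫ n; keeps gene weights interpretable |

Cross-validation criterion: mean misclassification error, with ties broken
by smaller mean panel size, then smaller α, then smaller c — preferring the
sparsest, most conservative cell among equals. A fold whose selection is
empty scores the majority-class error and is flagged, keeping the grid
complete. Both parameters are tuned jointly on shared folds (not nested),
so cells are compared on identical splits; after tuning, selection is
re-fit on the full training data at the optimum and the classifier is
trained on the final panel. Everything is seeded; refits are
byte-reproducible.

## Integrative correlation filter

For two studies sharing a gene universe, gene k's pair vector in each study
holds its Pearson correlations with every other common gene (self
excluded); the IC score is the correlation between the two vectors, and
genes strictly below the median IC are dropped (ties at the median
survive). Zero-variance genes have undefined correlations and are scored
0 — maximally incoherent — with a warning, erring toward removal since the
filter exists to exclude noise. The computation runs as standardized-matrix
products in configurable row blocks, so the G × G correlation matrices are
never held in full; ~7,000 genes × 100 samples is minutes on one CPU. In
the pipeline the filter is strictly training-era by default (training study
plus a designated companion); a `--paper-mode` flag instead computes IC
between training and test studies before any supervised step — the
original workflow ordering — and is documented as leaking test information.

## Synthetic data: what it does and does not emulate

Each gene set gets one latent factor per sample; a member gene is
loading·factor + noise, giving exchangeable within-set correlation, and
set-less background genes are independent noise at the same marginal
variance. With the default noise level (sqrt(1 − loading²)) genes have unit
variance and within-set correlation loading² (default loading 0.6 →
pairwise r = 0.36, a deliberately non-trivial co-expression level; an
explicit `noise_sd` changes the realized correlation to
loading²/(loading² + noise_sd²)). Signal is a mean shift of `effect_size`
marginal SDs on designated core genes of the signal sets in the diseased
class, so the reduction step has a planted answer. Two-study mode redraws
fresh samples from the same factor model and replaces a chosen fraction of
genes in the second study by independent noise (planted incoherence). A
Poisson count mode exists to exercise the CPM path but is not calibrated to
real RNA-seq dispersion.

What this does *not* emulate: heavy-tailed and heteroskedastic expression
noise, batch effects, overlapping pathways, unbalanced designs, or
count-level dispersion. Passing tests therefore demonstrate the
algorithmic and statistical correctness of the machinery under a clean,
exchangeable-correlation model — not performance on any real cohort.

## Operating characteristics measured here

The test suite and `scripts/acceptance.py` measure, at desk scale
(simulations of 30–1,200 genes, 20–60 samples, B = 400–10,000, 50–100
replicates — sizes chosen so the whole suite runs in well under an hour on
one CPU):

* Monte-Carlo set p-values agree with exhaustive enumeration within
  Monte-Carlo error, and the null type-I rate at 0.05 sits inside its exact
  binomial interval.
* The reduction removes essentially all non-core members of a planted
  50-gene set (median removal 1.0 at effect 1.5 SD, n = 30+30, c = 0.05).
  Its *sensitivity* to the planted cores, however, depends strongly on
  within-set correlation: correlation widens the permutation null of the
  complement, so the stopping rule fires while the weakest cores are still
  in the complement. At the generator default (r = 0.36) the measured
  median sensitivity is 0.6; with independent members the same code
  measures 0.9. This is a property of the complement-testing stopping rule
  itself, worth knowing before applying the method to tightly co-regulated
  pathways.
* The IC filter drops ≥ 80% of planted incoherent genes (100-replicate
  median) and matches a first-principles double-loop oracle to numerical
  precision.
* The full tuned pipeline, trained on one synthetic study and evaluated on
  an independent one, beats the majority-class baseline in every one of 50
  planted-signal replicates (median test error ≈ 0.16).

## Known limitations

* Binary phenotypes only; no paired designs, no multi-class metrics.
* Genes outside every annotated set are invisible to selection (background
  genes exist in the simulator precisely to probe this blind spot).
* The per-gene FDR machinery of the original SAM is out of scope; set
  p-values are tuning devices.
* Core recovery degrades with within-set correlation (see above) and the
  reduction inherits filter-style selection's weak control of false
  positive genes inside significant sets.
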