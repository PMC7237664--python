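# Methods

## The prediction problem

The package targets a population-cohort setting: n ≈ 900 adults, a plasma
metabolome of p ≈ 306 features (NMR concentrations and MS intensities,
treated as abstract continuous intensities here), eight demographic and
psychosocial covariates (sex, age, BMI, marital status, earthquake
house-damage category 0–4, antidepressant use, LSNS-6 social-network score,
social-capital score), and a CES-D depressive-symptom score — an integer in
[0, 60], also analyzed as binary traits at cutoffs ≥16 and ≥19.  The
analysis question is whether metabolites add predictive signal beyond
covariates, and which few metabolites carry it, without assuming the
metabolite–outcome relationships are linear.

## HSIC and the screening model

All dependency measurement uses the (biased) empirical Hilbert–Schmidt
independence criterion HSIC(u, v) = (n−1)⁻² tr(K̄ L̄), where K̄ = ΓKΓ with
Γ = I − (1/n)11ᵀ.  Kernel conventions: continuous variables are
standardized to zero mean, unit SD and use a Gaussian kernel with bandwidth
1 (the convention of the original HSIC Lasso method; exposed as a
parameter); categorical variables (sex, marital status, damage category,
antidepressant use, and binary outcomes) use the class-frequency-normalized
delta kernel K_ij = 1/n_c·1{labels equal}.  Reported dependency tables use
the Frobenius-normalized variant ⟨K̄/‖K̄‖, L̄/‖L̄‖⟩ ∈ [0, 1], scaled by a
configurable constant (default 10³) for readability; no particular absolute
scale is claimed for printed dependency values.

The screen solves the nonnegative Lasso over vectorized centered,
Frobenius-normalized Grams, reduced to ½αᵀQα − cᵀα + λ1ᵀα, α ≥ 0, with
Q_kl = ⟨K̄⁽ᵏ⁾, K̄⁽ˡ⁾⟩ and c_k = ⟨K̄⁽ᵏ⁾, L̄⟩.  Covariates compete with
metabolites as candidates.  Numerical choices:

* cyclic coordinate descent with exact coordinate minimizers; convergence
  declared at KKT residual ≤ 1e−8 (max_iter 10⁴ sweeps, warning and
  `converged=False` otherwise);
* exact duplicate directions (‖K̄ₖ − K̄ₗ‖² ≤ tol) have a flat objective
  along mass transfer; the solver returns the extreme point concentrating
  mass on the coordinate with larger c (ties to the lower index), so "one
  of two identical features" is deterministic;
* the selection size k is reached by geometric bisection of λ on
  (0, max c], warm-started downward; if k is skipped (features enter in
  groups) the largest achievable active set ≤ k is returned with a warning;
* zero-variance candidates are dropped with a warning, not an error;
* Grams are materialized into one (p, n²) buffer — the only
  quadratic-memory object (~2 GB at n ≈ 900, p ≈ 314).

## Predictors

Kernel ridge regression is solved natively in the dual,
β = (K + λ_r·m·I)⁻¹(y − ȳ), on features standardized by training-fold
statistics; predictions add ȳ back, so a constant training outcome is
reproduced exactly and predictions decay to the training mean far from the
data.  The λ_r·m·I scaling keeps λ_r comparable across fold sizes.  The
RBF bandwidth is parameterized as σ = s · (median pairwise distance of the
standardized training inputs), s ∈ {0.25, 0.5, 1, 2, 4}; λ_r ∈ {10⁻⁴ … 10}
log-spaced.  Binary traits use scikit-learn's soft-margin RBF SVC with
γ = 1/(2σ²), C ∈ {10⁻² … 10³}; the wrapper exposes continuous decision
values, and AUC is computed from those (no probability calibration).

## Nested cross-validation

One seeded fold plan (outer 5-fold; per outer training set a first inner
5-fold; per first-inner training set a second inner 5-fold) is shared by
every model.  Folds are formed by shuffle-then-slice, sizes differing by at
most one; binary analyses stratify so per-fold class counts differ by at
most one (whether the original protocol stratified is unknown; stratifying
avoids empty-class folds).  Models with a tunable selection stage tune it
in the first inner loop, scoring each candidate with predictor parameters
tuned in the second inner loop; single-stage models tune in the first
inner loop only.  The tuning score is the mean inner-fold value of the
outer metric (PCC or AUC).  With singleton grids the machinery reduces
exactly to flat 5-fold cross-validation (tested).  Folds whose metric is
undefined (constant predictions, single-class test fold) are recorded as
missing, not zero.  An audit set accumulates every subject index used for
selection, standardization and fitting; the harness asserts disjointness
from the held-out fold before scoring.

The k grid for HSIC Lasso defaults to {5, 10, 15, 20, 30, 50}; the Lasso
λ grid to {0.001 … 0.3} on standardized features; PLS components
{1 … 10}; SPLS components {1, 2, 3, 5} × η ∈ {0.1 … 0.9}.  The grid
contents are this package's declared defaults, since only the identity of
the tuned parameters is standard.  SPLS is implemented natively (soft-thresholded
NIPALS directions at η times the largest |Xᵀy| entry, final regression
through the retained scores) since no installed package provides it.
Random forest (500 trees, tuned mtry) and a two-hidden-layer 128-ReLU
neural network are optional baselines delegated to scikit-learn.

## Cohort statistics

Group comparisons at a score cutoff use pooled-variance two-sample t tests
for continuous covariates and two-sided Fisher exact tests for categorical
ones.  The Fisher tests enumerate all r×2 tables with the observed margins;
point probabilities are multivariate-hypergeometric masses computed in log
space from log-binomials, and the two-sided p sums probabilities
≤ (1 + 1e−7) × the observed table's (probability-mass method, the dominant
software convention).  The enumerator asserts its probabilities sum to 1
within 1e−9.  The last two free cells are a vectorized grid, so a 5×2
table over ~900 subjects enumerates in seconds; a budget guard (10⁹ table
evaluations) raises with a pointer to the seeded Monte Carlo fallback,
which reports a 95% Wilson interval.

## The synthetic cohort generator

Real cohort data of this kind are access-restricted, so the generator
emulates their statistical shape rather than any biological mechanism:

* metabolites are unit-variance Gaussians; redundancy blocks (default 10
  blocks of 3) share a latent factor giving within-block pairwise
  correlation ρ (default 0.6), emulating within-pathway correlation;
* covariate marginals are patterned on the cohort's demographic table
  (e.g. damage-category frequencies, LSNS-6 ≈ N(15.5, 5.6) clipped to
  [0, 30]);
* the outcome is latent = intercept + Σ covariate effects + Σ 3.0·g(z) +
  N(0, 4²), rounded and clipped to [0, 60].  The links g cycle through
  {x², sin(πx), 1{x > 0.5}, x} over the causal metabolites, so a purely
  even x² link — invisible to linear screens — is always present.  Effect
  size 3.0 per link and noise SD 4 put the planted metabolite signal at
  roughly the same order as the noise, a realistic regime for cohort
  metabolomics; the intercept 5.5 makes the ≥16 cutoff split the default
  cohort roughly 1:2 high:low, matching the observed prevalence;
* missing-outcome and unreliable-answer exclusions are independent
  Bernoulli flags (only marginal exclusion counts are known for the real
  cohort), removed by listwise deletion.

What the generator does **not** emulate: instrument artifacts and
batch effects, skewed or heavy-tailed intensity distributions,
metabolite–covariate dependence (e.g. sex–metabolite coupling), and any
real biochemical pathway structure.  Passing benchmarks therefore show
that the machinery recovers planted sparse nonlinear signal under
realistic dimensions and noise — not that real depressive symptoms are
predictable at any particular accuracy.

## Benchmark battery and problem sizes

The acceptance script and the corresponding tests run, from scratch:

* exact Fisher p-values of the published demographic count tables (the one
  part of the original results computable without the restricted data);
* the coordinate-descent solver against an independent bound-constrained
  QP solve (L-BFGS-B) on 50 random problems (p ≤ 10, n ≤ 30): objective
  gap ≤ 1e−8 and KKT residuals certified;
* duplicate-feature suppression over 100 random trials;
* planted-signal recovery at n = 400, p = 100: the 10-feature HSIC
  selection versus a linear Lasso-path top-10, 20 seeds.  In this scenario
  the five causal metabolites (default link cycle) are the only signal —
  covariate effects are off so the stated five features, not ~11 signal
  carriers, compete for the ten slots;
* nested-CV ordering (HSIC Lasso + kernel ridge vs. Lasso) on 20 seeded
  default-signal cohorts scaled to n = 300, p = 60 with reduced grids
  (k ∈ {5, 10, 20}, σ-scale ∈ {0.5, 1, 2}, λ_r ∈ {10⁻³ … 1}) — the full
  897 × 306 protocol is supported but this scale keeps the battery in
  minutes;
* screen calibration: 50 seeds × 100 planted-null metabolites at n = 200;
  the covariate-adjusted linear screen's t test is exact under the
  generator's Gaussian features, so retention should sit in the binomial
  band around 5%.

## Known limitations

* The sine link sin(πz) oscillates with period 2 in standardized units;
  a bandwidth-1 Gaussian kernel attenuates dependency at that frequency,
  so the sine-linked metabolite is the hardest to recover at the default
  effect size — a property of the kernel convention, visible in the
  recovery benchmark's misses.
* The biased HSIC estimator is used throughout (no U-statistic correction,
  no permutation p-values); dependency tables are descriptive.
* The Fisher enumerator supports r ≤ 6 rows; beyond the table budget the
  Monte Carlo fallback is approximate (with a reported interval).
* Printed dependency-table values depend on the kernel and scaling
  conventions above; they are comparable within a table, not across
  studies.
* Logistic adjusted regressions can fail under separation (rare events at
  cohort scale, e.g. antidepressant use); such features are flagged and
  skipped rather than imputed.
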