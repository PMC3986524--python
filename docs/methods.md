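# Methods

## Model and statistic

The working model for n subjects is `Y = X β₁ + Z β₂ + ε`: `Y` (n × p)
holds the target phenotypes (e.g. ROI-averaged fMRI contrast values), `X`
(n × q₁) additive SNP dosages, `Z` (n × q₂) nuisance covariates with an
intercept as the first column, and ε Gaussian noise.  With q₁ ≫ n the
quantity of interest is not any single coefficient but the *out-of-sample
predictive power* of the genetic block as a whole, measured by the
cross-validated coefficient of determination

    CV-R² = 1 − mean over splits of ‖y_test − ŷ_test‖² / ‖y_test − Z_test β̂₂‖²,

the mean being taken over the per-split RSS *ratios* before subtraction
from 1, and the denominator being the uncentered squared norm of the
covariate-adjusted test target (no additional recentering).  This is a
model-comparison statistic against the covariate-only model and is
unbounded below: an overfit model routinely scores negative on held-out
data, which is the expected behaviour of the permutation null in the
q₁ ≫ n regime rather than a pathology.

## Estimation pipeline

The default pipeline is: (1) an optional collinearity filter that drops
constant columns and any column whose absolute Pearson correlation with an
already-kept column exceeds 1 − tol (tol defaults to 1e-6; duplicates keep
the lowest index); (2) univariate screening retaining the K columns with
the largest simple-regression F statistic, F = r²(n−2)/(1−r²), with ties
resolved to the lowest index so selection is deterministic; (3) ridge
regression with an unpenalized intercept, solved in closed form through
the primal normal equations when n ≥ K and through the n × n dual system
otherwise.  The penalty α is applied unscaled (no multiplication by n or
K), i.e. the objective is ‖y − Xw − c‖² + α‖w‖².  Screening and filtering
are fit on the *training* rows of each outer split only; fitting them on
the full sample would leak test information and invalidate the permutation
null.

When a hyper-parameter grid is declared, every outer training split runs
its own exhaustive search over the grid (nested CV): candidates are scored
by mean R² over 5 near-equal folds obtained from a deterministic shuffle
seeded by (outer seed, split index); ties keep the first candidate in axis
enumeration order.  Components are addressed by registry key or by a
`DYNAMIC_IMPORT::module.Attr` plugin reference resolved lazily at worker
start, so the coordinating process never needs plugin code installed.

The three built-in components are implemented directly on numpy/scipy —
a permutation run refits the pipeline ~10⁵ times and per-fit overhead
dominates — and each is verified against its scikit-learn counterpart
(`f_regression`, `Ridge`) in the test suite.

## Outer cross-validation

Outer splits are shuffle-split subsamplings (scikit-learn `ShuffleSplit`)
with n_iter = 10 iterations and a 20% test fraction by default; the test
size is fixed to round(fraction·n) subjects.  Successive iterations are
independent subsamplings, so test sets may overlap across iterations.  All
splits are deterministic in the descriptor's CV seed and are identical for
every permutation and phenotype.

## Covariates and permutations

Standard learning machinery has no notion of nuisance covariates, so they
are handled by residualization.  In the default `full_sample` mode the
target is the OLS residual R_{Y|Z} computed once on the full sample; the
permuted target for permutation b shuffles R_{Y|Z} and residualizes the
result against Z a second time (the Anderson–Robinson approximation of the
exact covariate-aware permutation test).  Both projections use a
minimum-norm least-squares solve, so rank-deficient Z is handled; the
residual is orthogonal to Z by construction and the second projection can
only shrink its norm.

The printed form of the CV-R² equation estimates β₂ within each training
split.  The package exposes this as `covariate_mode: "per_fold"`, in which
β₂ is refit on each outer training set and applied to its test set.  The
default remains `full_sample` because the permutation null is *defined* on
full-sample residuals, and observed and permuted statistics must be
constructed identically for the test to be coherent; the two modes agree
closely on well-conditioned data and exactly when Z is the intercept
alone.

Permutation b of {0..n−1} is a pure function of (base_seed, b, n) — a
counter-based stream seeded by the pair (base_seed, b) — and never of the
phenotype index or worker identity.  The max-statistic correction below is
only valid if the *same* shuffle b is applied to every phenotype, so this
coupling is load-bearing.  Index b = 0 is reserved for the identity
(observed data).

## Inference

With B permutations, `p_uncorrected = (1 + #{b : null_b ≥ observed}) /
(B + 1)`: the observed arrangement counts as one permutation, so p = 0 is
impossible and the smallest achievable value is 1/(B+1); ties count
against rejection.  Family-wise error over the p phenotypes is controlled
by the Westfall–Young max-statistic: `p_fwer` uses the per-permutation
maximum of the statistic over phenotypes as its reference distribution,
which dominates every per-phenotype null column elementwise, so
p_fwer ≥ p_uncorrected always.  The saved null table allows re-deriving
p-values for a restricted phenotype family without recomputation.

## Execution model

The inference tiles {phenotypes} × {permutations 1..B} into blocks of
`permutations_per_task` consecutive permutation ids; the first block of
each phenotype also carries id 0.  Map tasks are pure functions of
(task, dataset, descriptor); the reduce fills a (B × p) table and its
per-permutation maximum, and is associative and commutative, so any
ordering, grouping or worker count yields a bit-identical result.  A
completed task is appended to an on-disk newline-delimited JSON ledger
(with a checksum) before acknowledgment; on restart, valid ledger records
are skipped and the rest re-queued.  At-least-once scheduling plus
idempotent maps gives exactly-once results.  Corrupt ledger lines are
dropped and their tasks re-run.  Parallelism is across tasks only — the
numerics inside one task are single-threaded — which keeps results
independent of scheduling.  Interruption for testing is exposed as a
`stop_after_tasks` argument rather than signal delivery, making the resume
path deterministic.

## Synthetic cohorts

The generator emulates the data this analysis consumes.  Genotypes: MAFs
uniform on [0.05, 0.5]; two latent standard-normal allele draws per SNP
thresholded at Φ⁻¹(maf) give Binomial(2, maf), Hardy–Weinberg-consistent
dosages; an optional AR(1) correlation ρ between adjacent latent columns
(Gaussian copula) mimics local LD.  Covariates: intercept; sex Bernoulli
0.5; age uniform on a two-year adolescent span (14–16); handedness
Bernoulli 0.9; acquisition center uniform over 8 sites, one-hot encoded
with the lexicographically first level dropped.  Covariate effects are
drawn nonzero by default, deliberately: a pipeline that ignored Z would
show inflated statistics and fail the calibration tests.  Phenotypes:
y_j = X w_j + Z b_j + ε with w_j supported on a shared causal set; the
scaling of w_j solves a quadratic in the empirical moments so that
Var(X w_j)/Var(y_j) equals the requested g² *exactly in-sample*, leaving
no Monte-Carlo slack in tests keyed to g².  Missing genotype entries are
masked uniformly after phenotype construction.

What the generator does not emulate: realistic LD panels from reference
haplotypes, population stratification or kinship, dominance or epistatic
effects, and non-Gaussian phenotype noise.  Passing tests therefore
demonstrate the statistical machinery (calibration, power against a linear
additive signal, error control), not robustness to confounding by
population structure.

## Numerical and design choices

- Missing dosage tokens: `NA`, `NaN`, empty cell.  Median imputation uses
  the per-column median over observed entries (numpy's lower-midpoint
  average for even counts; fractional dosages are permitted).  Imputation
  follows SNP filtering when the optional MAF/HWE/missing-rate pre-filter
  (thresholds 0.05, 0.001, 0.05) is enabled; the filter is off by default
  since panels are usually pre-filtered upstream.
- Categorical covariates: reference level is the lexicographically first —
  deterministic without user input.  After encoding, linearly dependent
  columns are removed by a greedy left-to-right Gram–Schmidt scan so Z has
  full column rank (the intercept, scanned first, is always kept).
- Residualization requires n > q₂; a zero-variance test-split target is an
  error that suggests enlarging the test fraction; constant phenotypes are
  rejected at load time.
- Descriptor schema: required keys {with_covariates, n_permutations,
  permutations_per_task, score, cv, pipeline}, optional {grid,
  covariate_mode}; unknown keys are hard errors.  Defaults:
  permutations_per_task 1, n_iter 10, test_fraction 0.2, seed 0.  B must
  be divisible by permutations_per_task.  The score metric accepts only
  `"r2"`.
- The observed statistic is scheduled inside each phenotype's first
  permutation block rather than as a separate task; this keeps the
  task-tiling invariant trivial.

## Problem sizes used in validation

The validation studies run at deliberately small scale: type-I calibration
uses 200 null cohorts of n=100 subjects × 200 SNPs with B=99 permutations
(rejection rate at α=0.05 checked against the binomial 99% band
[0.02, 0.09]); power uses 10 replicates at n=400 × 2000 SNPs, 20 causal,
g²=0.6, B=99; the negative-null-mean check uses one n=100 × 2000 cohort.
These sizes were chosen so that the full suite completes in minutes on a
single core while each check retains enough Monte-Carlo resolution to be
informative; the framework itself is size-agnostic and the task arithmetic
is validated at the full 14 × 10,000 configuration.

## Known limitations

Grid search assumes candidate values valid for every training split (e.g.
K not exceeding the post-filter column count).  The per-fold covariate
mode is provided for methodological comparison but permutations are always
generated from full-sample residuals.  The engine's ledger is local-file
based; distributing across machines would need only a shared append-only
store, since the reduce operator is already associative and commutative.
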