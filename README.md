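# cvperm

Permutation-based significance testing of cross-validated
genotype→phenotype prediction scores, with nuisance covariates and
family-wise error control across phenotypes.

## The problem

Imaging-genetics studies ask whether genome-wide genotypes, taken jointly,
predict a brain phenotype (for example the mean fMRI contrast value in an
anatomical region of interest) better than chance.  For *n* subjects the
working model is

```
Y = X β₁ + Z β₂ + ε
```

with `Y` the *n × p* phenotype matrix, `X` the *n × q₁* additive SNP dosage
matrix (values in {0, 1, 2}), and `Z` the *n × q₂* nuisance covariates
(acquisition center, sex, handedness, age, and an intercept).  Because
`q₁ ≫ n`, mass-univariate testing is insensitive and an unpenalized joint
fit is impossible; the statistic used instead is the **cross-validated
coefficient of determination** of a regularized multivariate pipeline,

```
CV-R² = 1 − mean over (train, test) splits of
        ‖Y_test − X_test β₁^train − Z_test β₂^train‖² / ‖Y_test − Z_test β₂^train‖²
```

i.e. one minus the mean ratio between the held-out residual sum of squares
of the genetic model and that of the covariate-only model.  A CV-R²
significantly above its permutation null is evidence that the phenotype is
predictable from genotype — a practical proxy for SNP-based heritability.
CV-R² can legitimately be *negative*: in high dimension an overfit model
predicts worse on unseen subjects than the non-informative model, which is
exactly what happens under permutation.

The package provides:

* a declarative **JSON descriptor** specifying the estimator pipeline
  (collinearity filter → univariate F-score K-best screening → ridge
  regression), the outer shuffle-split CV scheme, an optional
  hyper-parameter grid searched by an inner 5-fold CV, and the permutation
  plan; components can also be plugged in via `DYNAMIC_IMPORT::` references;
* covariate-aware permutations (Anderson–Robinson residual scheme): the
  target is the full-sample OLS residual `R_{Y|Z}`, each permutation
  shuffles it and residualizes against `Z` again;
* **Westfall–Young max-statistic correction**: the per-permutation maximum
  of CV-R² over all phenotypes is the reference distribution for
  family-wise-error corrected p-values;
* an embarrassingly parallel **map-reduce engine** (one task = one
  phenotype × one block of permutations) with an associative, commutative
  reduce and an append-only task ledger, so runs are parallel, resumable
  after interruption, and bit-identical to a serial run;
* a **synthetic cohort generator** planting a genetic effect of exact
  in-sample variance fraction, with realistic MAFs, Hardy–Weinberg
  genotypes, optional LD, multi-center covariate effects and missing
  entries.

## Worked example

```
$ cvperm simulate --n 200 --snps 500 --phenotypes 3 --causal 10 --g2 0.4 \
    --seed 7 --out cohort/
$ cvperm run --config examples/descriptors/roi_small.json \
    --phenotypes cohort/phenotypes.tsv --genotypes cohort/genotypes.tsv \
    --covariates cohort/covariates.tsv --categorical center \
    --workers 2 --seed 1 --out report.tsv
```

or, equivalently, from Python (`examples/03_permutation_inference.py`):

```
B = 99 permutations; mean null CV-R^2 = -0.525
phenotype    CV-R^2        p   p_fwer
roi_00       -0.007    0.010    0.010
roi_01       -0.107    0.010    0.020
roi_02       -0.210    0.030    0.070
```

Reading: the mean *null* CV-R² is strongly negative (permutation breaks the
genotype–phenotype link, so the overfit model loses badly out of sample).
The observed scores, although themselves slightly negative, sit at or near
the top of the null distribution: `roi_00` and `roi_01` reach
`p = 0.010`, the smallest value achievable with B = 99 (`1/(B+1)`), while
the weaker `roi_02` is suggestive but not family-wise significant once its
score is compared against the per-permutation maximum over the three
phenotypes (`p_fwer = 0.07`).  A slightly negative CV-R² can thus still
mark a significant genotype–phenotype association.

The `examples/` scripts each demonstrate one capability: cohort simulation
(01), the prediction score itself (02), full permutation inference (03),
and crash/resume fault tolerance (04).

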