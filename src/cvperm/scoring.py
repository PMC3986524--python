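"""Cross-validated prediction score (CV-R^2) for one target vector.

The statistic is

    CV-R^2 = 1 - mean over splits of  ||y_test - prediction||^2
                                      -------------------------
                                      ||y_test - Z_test b2||^2

i.e. one minus the mean over outer shuffle-split iterations of the ratio
between the test-set residual sum of squares of the genetic model and that
of the covariate-only model.  The mean is taken over the per-split RATIOS
before subtraction from 1, and the denominator is the uncentered squared
norm of the covariate-adjusted test target — no extra recentering.

CV-R^2 can be negative: in high dimension a poorly fitting linear model
predicts (much) worse on held-out data than the non-informative
covariate-only model, so a model performing at chance gets a negative score.

Two covariate modes exist.  In ``full_sample`` (default) the target handed
in is already residualized against Z on the full sample and the denominator
is simply ``||target_test||^2`` — this matches the construction of the
permutation null, so observed and permuted statistics are exchangeable.  In
``per_fold`` the covariate coefficients b2 are refit on each training split
and applied to its test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import ShuffleSplit

from .estimator import PipelineSpec, fit_pipeline
from .exceptions import DegenerateDataError
from .linstats import ResidualTarget, fit_ols

__all__ = ["FoldScheme", "ScoreResult", "make_splits", "cv_score"]


@dataclass(frozen=True)
class FoldScheme:
    """Deterministic outer shuffle-split partitions."""

    n_iter: int
    test_fraction: float
    seed: int
    splits: tuple[tuple[np.ndarray, np.ndarray], ...]


@dataclass(frozen=True)
class ScoreResult:
    cv_r2: float
    per_split_ratios: np.ndarray
    phenotype: int = 0
    permutation_id: int = 0


def make_splits(n: int, n_iter: int, test_fraction: float, seed: int) -> FoldScheme:
    """Build ``n_iter`` shuffle-split train/test partitions of ``n`` subjects.

    Successive iterations are independent subsamplings (test sets may
    overlap across iterations).  |test| = round(test_fraction * n).
    """
    n_test = int(round(test_fraction * n))
    if n_test < 1:
        raise DegenerateDataError(
            f"test_fraction={test_fraction} gives an empty test set for n={n}"
        )
    if n - n_test < 2:
        raise DegenerateDataError(
            f"n={n} leaves fewer than 2 training subjects per split"
        )
    ss = ShuffleSplit(n_splits=n_iter, test_size=n_test, random_state=seed)
    splits = tuple(
        (np.sort(tr), np.sort(te)) for tr, te in ss.split(np.zeros((n, 1)))
    )
    return FoldScheme(n_iter=n_iter, test_fraction=test_fraction, seed=seed, splits=splits)


def cv_score(
    target: ResidualTarget,
    X: np.ndarray,
    spec: PipelineSpec,
    folds: FoldScheme,
    *,
    Z: np.ndarray | None = None,
    covariate_mode: str = "full_sample",
) -> ScoreResult:
    """CV-R^2 of the pipeline for one (possibly permuted) target.

    Parameters
    ----------
    target
        The working target.  In ``full_sample`` mode this is already
        orthogonal to the covariates.
    X
        (n, q1) genotype matrix shared by all permutations.
    spec
        Compiled pipeline (with optional grid axes; the grid is searched
        inside every outer training split — nested CV).
    folds
        Outer shuffle-split scheme from :func:`make_splits`.
    Z
        Covariate design; required in ``per_fold`` mode.

    Raises
    ------
    DegenerateDataError
        If a test split's target has exactly zero variance (enlarge
        ``test_fraction``).
    """
    y = target.values
    per_fold = covariate_mode == "per_fold"
    if per_fold and Z is None:
        raise ValueError("per_fold covariate mode requires Z")
    ratios = np.empty(len(folds.splits))
    for i, (train_idx, test_idx) in enumerate(folds.splits):
        y_train = y[train_idx]
        y_test = y[test_idx]
        if per_fold:
            assert Z is not None
            beta2 = fit_ols(y_train, Z[train_idx]).coefficients
            y_train = y_train - Z[train_idx] @ beta2
            y_test = y_test - Z[test_idx] @ beta2
        denom = float(y_test @ y_test)
        if denom == 0.0:
            raise DegenerateDataError(
                f"test split {i} has a zero-variance target; enlarge "
                "test_fraction or check the phenotype"
            )
        fitted = fit_pipeline(
            X[train_idx], y_train, spec, seed_parts=(folds.seed, i)
        )
        err = y_test - fitted.predict(X[test_idx])
        ratios[i] = float(err @ err) / denom
    return ScoreResult(
        cv_r2=float(1.0 - ratios.mean()),
        per_split_ratios=ratios,
        phenotype=target.source_phenotype,
        permutation_id=target.permutation_id,
    )
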