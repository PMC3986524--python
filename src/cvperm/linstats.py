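"""Ordinary-least-squares residualization and permutation targets.

A permutation test of a prediction score must not shuffle variance that is
explained by nuisance covariates (scanner site, sex, age, ...): doing so
breaks exchangeability and biases the null.  The scheme implemented here is
the residual-permutation approximation of Anderson & Robinson: the target
phenotype is first residualized against the covariate design ``Z`` on the
full sample; under permutation ``b`` the residual vector is shuffled and
residualized against ``Z`` a second time, so that every permuted target is
again orthogonal to the covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError

__all__ = [
    "FittedLinearModel",
    "ResidualTarget",
    "fit_ols",
    "residualize",
    "make_permutation",
    "permuted_target",
]


@dataclass(frozen=True)
class FittedLinearModel:
    """Least-squares fit of a target on a design matrix.

    ``coefficients`` is the minimum-norm solution when the design is
    rank-deficient; ``design_rank`` is the numerical rank used.
    """

    coefficients: np.ndarray
    design_rank: int


@dataclass(frozen=True)
class ResidualTarget:
    """A covariate-orthogonal target vector for the estimation pipeline.

    ``permutation_id`` 0 denotes the observed (unpermuted) data.
    """

    values: np.ndarray
    source_phenotype: int = 0
    permutation_id: int = 0


def fit_ols(y: np.ndarray, Z: np.ndarray) -> FittedLinearModel:
    """Least-squares fit of ``y`` on ``Z`` (minimum-norm on rank deficiency)."""
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    return FittedLinearModel(coefficients=beta, design_rank=int(rank))


def residualize(
    y: np.ndarray,
    Z: np.ndarray,
    *,
    source_phenotype: int = 0,
    permutation_id: int = 0,
) -> ResidualTarget:
    """Project ``y`` onto the orthogonal complement of the columns of ``Z``.

    Parameters
    ----------
    y : (n,) array
        Target vector.
    Z : (n, q2) array
        Covariate design including an intercept column.

    Returns
    -------
    ResidualTarget
        ``y - Z @ beta`` with ``beta`` the least-squares solution.

    Raises
    ------
    DegenerateDataError
        If ``n <= q2``: the residuals would be identically zero and every
        downstream statistic undefined.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = y.shape[0]
    if Z.ndim != 2 or Z.shape[0] != n:
        raise ValueError(f"Z must be (n, q2) with n={n}, got {Z.shape}")
    if n <= Z.shape[1]:
        raise DegenerateDataError(
            f"cannot residualize: n={n} subjects <= q2={Z.shape[1]} covariate "
            "columns (residuals would be identically zero)"
        )
    fit = fit_ols(y, Z)
    return ResidualTarget(
        values=y - Z @ fit.coefficients,
        source_phenotype=source_phenotype,
        permutation_id=permutation_id,
    )


def make_permutation(b: int, base_seed: int, n: int) -> np.ndarray:
    """Deterministic permutation of ``{0..n-1}`` for permutation index ``b``.

    The permutation is a function of ``(base_seed, b, n)`` only — never of
    the phenotype index or the worker identity — so that the same shuffle
    ``b`` is applied to every phenotype.  The max-statistic reduce used for
    family-wise error correction is only valid under that coupling.

    ``b = 0`` is reserved for the identity (the observed data).
    """
    if b < 0:
        raise ValueError("permutation index must be >= 0")
    if base_seed < 0:
        raise ValueError("base_seed must be a non-negative integer")
    if b == 0:
        return np.arange(n)
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, b)))
    return rng.permutation(n)


def permuted_target(r: ResidualTarget, perm: np.ndarray, Z: np.ndarray) -> ResidualTarget:
    """Shuffle a residual target and re-orthogonalize it against ``Z``.

    The output is ``residualize(r.values[perm], Z)``; since projection is a
    contraction, its norm never exceeds that of ``r``.
    """
    return residualize(
        r.values[np.asarray(perm)],
        Z,
        source_phenotype=r.source_phenotype,
        permutation_id=r.permutation_id,
    )
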