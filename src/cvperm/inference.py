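"""Permutation p-values, uncorrected and family-wise-error corrected.

The uncorrected p-value of phenotype j compares its observed CV-R^2 to its
own permutation scores; the corrected p-value compares it to the
per-permutation maximum over ALL phenotypes (Westfall-Young max-statistic),
which controls the family-wise error rate under the permutation null.

Both use the add-one convention p = (1 + #{b: null_b >= observed}) / (B + 1)
— the observed arrangement counts as one permutation, so p = 0 is
impossible and the smallest achievable value is 1 / (B + 1).  Ties count
against rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import NullTable

__all__ = ["ResultReport", "p_uncorrected", "p_fwer", "make_report"]


@dataclass
class ResultReport:
    """Per-phenotype observed statistic and p-values for one inference run."""

    phenotype_names: list[str]
    observed: np.ndarray
    p_uncorrected: np.ndarray
    p_fwer: np.ndarray
    B: int
    null_table: NullTable | None = None


def p_uncorrected(observed: float, null_column: np.ndarray) -> float:
    """(1 + #{b : null[b] >= observed}) / (B + 1)."""
    null_column = np.asarray(null_column, dtype=float)
    B = null_column.shape[0]
    return float(1 + np.count_nonzero(null_column >= observed)) / (B + 1)


def p_fwer(observed: float, max_null: np.ndarray) -> float:
    """Corrected p-value against the per-permutation max over phenotypes."""
    return p_uncorrected(observed, max_null)


def make_report(
    table: NullTable,
    phenotype_names: list[str] | None = None,
    scope: list[int] | None = None,
) -> ResultReport:
    """Build the per-phenotype report from a complete null table.

    ``scope`` restricts the family over which the max-statistic is taken
    (and the phenotypes reported); default is all phenotypes.
    """
    if not table.complete:
        raise ValueError("null table is incomplete; run the engine to completion")
    idx = list(range(table.p)) if scope is None else list(scope)
    if phenotype_names is None:
        phenotype_names = [f"phenotype_{j}" for j in idx]
    elif len(phenotype_names) == table.p and scope is not None:
        phenotype_names = [phenotype_names[j] for j in idx]
    max_null = np.max(table.null_scores[:, idx], axis=1)
    observed = table.observed[idx]
    return ResultReport(
        phenotype_names=phenotype_names,
        observed=observed,
        p_uncorrected=np.array(
            [p_uncorrected(observed[i], table.null_scores[:, j]) for i, j in enumerate(idx)]
        ),
        p_fwer=np.array([p_fwer(o, max_null) for o in observed]),
        B=table.B,
        null_table=table,
    )
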