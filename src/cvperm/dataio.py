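"""Input/output: align phenotypes, genotypes and covariates; persist results.

Inputs are plain tabular files sharing a subject-identifier column:

* phenotypes — CSV/TSV, one column per target (e.g. ROI-mean fMRI contrast);
* genotypes  — CSV/TSV of additive dosages in {0,1,2} (fractional values
  tolerated), or a PLINK ``.raw`` additive-coding export (header row, six
  leading metadata columns, ``NA`` for missing);
* covariates — CSV/TSV of mixed categorical/continuous confounds.

The three tables are inner-joined on subject id and sorted canonically, so
loading is insensitive to input row order.  Categorical covariates are
one-hot encoded with the lexicographically first level as the dropped
reference; an all-ones intercept is prepended; linearly dependent encoded
columns are removed so Z has full column rank.  Remaining missing genotype
entries are replaced by the per-SNP median over observed subjects.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DataError, DegenerateDataError, FormatError

__all__ = [
    "Dataset",
    "CovariateSpec",
    "load_dataset",
    "impute_median",
    "encode_covariates",
    "snp_filter",
    "write_report",
    "read_null_table",
]

MISSING_TOKENS = ["NA", "NaN", "nan", ""]

PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class Dataset:
    """Aligned (Y, X, Z) matrices for n subjects.

    ``Y`` (n, p) target phenotypes; ``X`` (n, q1) genotype dosages in
    [0, 2]; ``Z`` (n, q2) encoded covariates whose first column is the
    all-ones intercept.  Rows of the three matrices refer to the same
    subjects in the same (canonically sorted) order.
    """

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    phenotype_names: list[str]
    snp_names: list[str]
    subject_ids: list[str]
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    def __post_init__(self) -> None:
        n = self.Y.shape[0]
        if not (self.X.shape[0] == n and self.Z.shape[0] == n):
            raise AlignmentError(
                f"row mismatch: Y has {n}, X has {self.X.shape[0]}, "
                f"Z has {self.Z.shape[0]} rows"
            )


@dataclass(frozen=True)
class CovariateSpec:
    """Which covariate columns are categorical vs continuous.

    Columns not listed are inferred from dtype (non-numeric => categorical).
    """

    categorical: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_table(path: str) -> pd.DataFrame:
    """Read a CSV/TSV/PLINK-raw table with the subject id as the index."""
    if path.endswith(".raw"):
        df = pd.read_csv(path, sep=r"\s+", na_values=MISSING_TOKENS, dtype=str)
        missing = [c for c in PLINK_RAW_META if c not in df.columns]
        if missing:
            raise FormatError(
                f"{path}: PLINK .raw file lacks metadata columns {missing}"
            )
        df = df.set_index("IID").drop(columns=[c for c in PLINK_RAW_META if c != "IID"])
        df.index = df.index.astype(str)
        return df
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, na_values=MISSING_TOKENS, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a subject-id column plus data columns")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def _to_numeric(df: pd.DataFrame, path: str, *, domain: tuple[float, float] | None = None) -> pd.DataFrame:
    try:
        out = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    if domain is not None:
        lo, hi = domain
        vals = out.to_numpy(dtype=float)
        bad = (vals < lo) | (vals > hi)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise FormatError(
                f"{path}: value {vals[i, j]} in column {out.columns[j]!r} "
                f"outside the dosage domain [{lo}, {hi}]"
            )
    return out


def load_dataset(
    phenotype_path: str,
    genotype_path: str,
    covariate_path: str,
    covariate_spec: CovariateSpec | None = None,
) -> Dataset:
    """Load, align and encode the three input tables.

    Subjects are inner-joined on their identifier and sorted; genotype
    missing entries are median-imputed; constant phenotypes are rejected
    (they make the prediction score undefined).
    """
    pheno = _to_numeric(_read_table(phenotype_path), phenotype_path)
    geno = _to_numeric(_read_table(genotype_path), genotype_path, domain=(0.0, 2.0))
    covs = _read_table(covariate_path)

    subjects = sorted(set(pheno.index) & set(geno.index) & set(covs.index))
    if not subjects:
        raise AlignmentError(
            "no subject identifier is shared by the phenotype, genotype and "
            "covariate files"
        )
    pheno = pheno.loc[subjects]
    geno = geno.loc[subjects]
    covs = covs.loc[subjects]

    Y = pheno.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise FormatError(f"{phenotype_path}: phenotypes contain missing values")
    if np.any(Y.std(axis=0) == 0.0):
        j = int(np.flatnonzero(Y.std(axis=0) == 0.0)[0])
        raise DegenerateDataError(
            f"phenotype {pheno.columns[j]!r} is constant across subjects"
        )
    X = impute_median(geno.to_numpy(dtype=float), column_names=list(geno.columns))
    Z, cov_names = encode_covariates(covs, covariate_spec)
    return Dataset(
        Y=Y,
        X=X,
        Z=Z,
        phenotype_names=list(pheno.columns),
        snp_names=list(geno.columns),
        subject_ids=subjects,
        covariate_names=cov_names,
    )


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def impute_median(M: np.ndarray, column_names: list[str] | None = None) -> np.ndarray:
    """Replace missing (NaN) entries by the per-column median over observed ones.

    Observed entries are unchanged; the operation is idempotent.  A fully
    missing column is an error naming the column.
    """
    M = np.asarray(M, dtype=float)
    out = M.copy()
    nan_mask = np.isnan(out)
    if not nan_mask.any():
        return out
    all_missing = nan_mask.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        name = column_names[j] if column_names else f"#{j}"
        raise DegenerateDataError(f"column {name!r} has no observed values")
    cols = np.where(nan_mask.any(axis=0))[0]
    for j in cols:
        out[nan_mask[:, j], j] = np.nanmedian(M[:, j])
    return out


def encode_covariates(
    covs: pd.DataFrame, spec: CovariateSpec | None = None
) -> tuple[np.ndarray, list[str]]:
    """Encode a covariate table into a full-column-rank design with intercept.

    Categorical columns become indicator columns for every level except the
    lexicographically first (the reference).  Continuous columns pass
    through.  An all-ones intercept column is prepended, and any encoded
    column linearly dependent on the preceding ones is dropped.
    """
    spec = spec or CovariateSpec()
    cols: list[np.ndarray] = [np.ones(len(covs))]
    names: list[str] = ["intercept"]
    for col in covs.columns:
        series = covs[col]
        declared_cat = col in spec.categorical
        declared_cont = col in spec.continuous
        if not declared_cat and not declared_cont:
            numeric = pd.to_numeric(series, errors="coerce")
            declared_cont = not numeric.isna().any()
        if declared_cont:
            values = pd.to_numeric(series, errors="coerce")
            if values.isna().any():
                raise FormatError(f"continuous covariate {col!r} has non-numeric cells")
            cols.append(values.to_numpy(dtype=float))
            names.append(col)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:  # lexicographically first level = reference
                cols.append((series.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{col}={level}")
    Z = np.column_stack(cols)
    keep = _independent_columns(Z)
    return Z[:, keep], [names[j] for j in keep]


def _independent_columns(Z: np.ndarray, rtol: float = 1e-10) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns."""
    n = Z.shape[0]
    basis = np.empty((n, 0))
    keep: list[int] = []
    for j in range(Z.shape[1]):
        v = Z[:, j]
        if basis.shape[1]:
            v = v - basis @ (basis.T @ v)
        norm = np.linalg.norm(v)
        if norm > rtol * max(1.0, np.linalg.norm(Z[:, j])):
            keep.append(j)
            basis = np.column_stack([basis, v / norm])
    return keep


def snp_filter(
    X: np.ndarray,
    maf_min: float = 0.05,
    hwe_p: float = 0.001,
    missing_max: float = 0.05,
) -> np.ndarray:
    """Standard SNP quality filters; returns indices of SNPs passing all three.

    Keeps a SNP iff minor allele frequency > ``maf_min``, the 1-df chi-square
    Hardy-Weinberg goodness-of-fit p-value is >= ``hwe_p``, and the fraction
    of missing entries is < ``missing_max``.  Dosages are rounded to the
    nearest genotype class for the counts.  Off by default in the pipeline:
    genotype panels are usually pre-filtered with standard tooling.
    """
    from scipy.stats import chi2

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    miss = np.isnan(X).mean(axis=0)
    keep = miss < missing_max
    p_alt = np.nanmean(X, axis=0) / 2.0  # frequency of the counted allele
    maf = np.minimum(p_alt, 1.0 - p_alt)
    keep &= maf > maf_min
    G = np.rint(X)
    obs = np.stack([np.nansum((G == g) & ~np.isnan(X), axis=0) for g in (0.0, 1.0, 2.0)])
    n_obs = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = obs[2] / n_obs + 0.5 * obs[1] / n_obs  # counted-allele frequency
        exp = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n_obs
        stat = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0).sum(axis=0)
    pvals = chi2.sf(stat, df=1)
    keep &= pvals >= hwe_p
    return np.where(keep)[0]


# ---------------------------------------------------------------------------
# Result persistence
# ---------------------------------------------------------------------------

def write_report(report, path: str) -> None:
    """Write a result report as a TSV plus a JSON null-table sidecar.

    The TSV has one row per phenotype with the observed CV-R^2 and both
    p-values; the sidecar ``<path>.null.json`` stores the complete
    permutation null table so corrected p-values can be re-derived later.
    """
    rows = pd.DataFrame(
        {
            "phenotype": report.phenotype_names,
            "cv_r2": np.asarray(report.observed, dtype=float),
            "p_uncorrected": np.asarray(report.p_uncorrected, dtype=float),
            "p_fwer": np.asarray(report.p_fwer, dtype=float),
        }
    )
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    rows.to_csv(path, sep="\t", index=False)
    if report.null_table is not None:
        nt = report.null_table
        sidecar = {
            "schema": "cvperm-nulltable-v1",
            "B": int(report.B),
            "phenotype_names": list(report.phenotype_names),
            "observed": np.asarray(nt.observed).tolist(),
            "null_scores": np.asarray(nt.null_scores).tolist(),
        }
        with open(path + ".null.json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh)


def read_null_table(path: str):
    """Load a null-table sidecar written by :func:`write_report`.

    Returns ``(NullTable, phenotype_names)``.
    """
    from .engine import NullTable

    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != "cvperm-nulltable-v1":
        raise DataError(f"{path}: unrecognized null-table schema")
    nt = NullTable(
        observed=np.asarray(doc["observed"], dtype=float),
        null_scores=np.asarray(doc["null_scores"], dtype=float),
    )
    return nt, list(doc["phenotype_names"])
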