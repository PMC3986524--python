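"""Synthetic imaging-genetics datasets with a planted genetic effect.

Real genotype/imaging cohorts of the kind this package targets are
access-controlled, so every stage is exercised on synthetic data that
reproduces the statistical structure the analysis assumes:

* additive dosage genotypes in {0, 1, 2}, Hardy-Weinberg consistent, with
  minor allele frequencies drawn uniformly from a configurable range and an
  optional first-order correlation between adjacent SNPs (a crude stand-in
  for linkage disequilibrium, via a Gaussian copula on the latent alleles);
* covariates mimicking a multi-center adolescent cohort: acquisition
  center (8 sites), sex, handedness (90% right-handed), and age on a
  two-year span — all with nonzero effects on the phenotypes by default, so
  a pipeline that ignored the covariates would show inflated statistics;
* p correlated phenotype columns, each y_j = X w_j + Z b_j + eps with the
  weights w_j supported on a shared causal SNP set, scaled so that the
  in-sample variance fraction Var(X w_j) / Var(y_j) equals the requested
  g^2 exactly (empirical variances, no Monte-Carlo slack);
* optional uniformly-missing genotype entries to exercise median
  imputation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataio import CovariateSpec, Dataset, encode_covariates, impute_median
from .exceptions import ConfigError

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticData", "generate", "write_files"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    ``genetic_variance_fraction`` (g^2) is the in-sample fraction of each
    phenotype's variance explained by the planted genetic effect; ``ld_decay``
    is the latent correlation between adjacent SNPs.
    """

    n_subjects: int
    n_snps: int
    n_phenotypes: int = 1
    n_causal_snps: int = 10
    genetic_variance_fraction: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_centers: int = 8
    missing_rate: float = 0.0
    ld_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.genetic_variance_fraction < 1.0:
            raise ConfigError("genetic_variance_fraction must be in [0, 1)")
        if self.n_causal_snps > self.n_snps:
            raise ConfigError("n_causal_snps cannot exceed n_snps")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5:
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigError("ld_decay must be in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: causal SNP indices and per-phenotype weights."""

    causal_indices: np.ndarray
    weights: np.ndarray  # (n_causal, n_phenotypes), scaled
    mafs: np.ndarray


@dataclass
class SyntheticData:
    """A generated cohort: analysis-ready matrices plus raw writable tables."""

    dataset: Dataset  # genotypes median-imputed, covariates encoded
    phenotypes: pd.DataFrame
    genotypes_raw: pd.DataFrame  # may contain missing entries
    covariates: pd.DataFrame
    truth: GroundTruth


def _latent_ar1(rng: np.random.Generator, n: int, q: int, rho: float) -> np.ndarray:
    """n x q standard-normal matrix with AR(1) correlation across columns."""
    e = rng.standard_normal((n, q))
    if rho == 0.0:
        return e
    g = np.empty_like(e)
    g[:, 0] = e[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, q):
        g[:, j] = rho * g[:, j - 1] + scale * e[:, j]
    return g


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one cohort; bit-identical for identical (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    n, q = spec.n_subjects, spec.n_snps

    # genotypes: two latent allele draws per SNP => Binomial(2, maf) margins
    mafs = rng.uniform(*spec.maf_range, size=q)
    thresh = norm.ppf(mafs)
    alleles = [
        (_latent_ar1(rng, n, q, spec.ld_decay) < thresh).astype(float)
        for _ in range(2)
    ]
    X = alleles[0] + alleles[1]

    # covariates: multi-center cohort structure
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(14.0, 16.0, size=n)
    handedness = (rng.random(n) < 0.9).astype(int)
    center = rng.integers(0, spec.n_centers, size=n)
    covariates = pd.DataFrame(
        {
            "sex": sex,
            "age": np.round(age, 3),
            "handedness": handedness,
            "center": [f"c{c:02d}" for c in center],
        },
        index=[f"s{i:05d}" for i in range(n)],
    )
    Z, cov_names = encode_covariates(
        covariates, CovariateSpec(categorical=("center",))
    )

    # planted effect: shared causal support, per-phenotype weights
    causal = np.sort(rng.choice(q, size=spec.n_causal_snps, replace=False))
    g2 = spec.genetic_variance_fraction
    p = spec.n_phenotypes
    W = np.zeros((spec.n_causal_snps, p))
    Y = np.empty((n, p))
    b_scale = 0.3  # nonzero covariate effects by design (tripwire for Z-blind pipelines)
    for j in range(p):
        b = rng.normal(0.0, b_scale, size=Z.shape[1])
        b[0] = rng.normal(0.0, 1.0)  # intercept offset
        eps = rng.standard_normal(n)
        u = Z @ b + eps
        if g2 > 0.0:
            w = rng.standard_normal(spec.n_causal_snps)
            s = X[:, causal] @ w
            c = _effect_scale(s, u, g2)
            W[:, j] = c * w
            Y[:, j] = c * s + u
        else:
            Y[:, j] = u

    # missingness mask applied after the phenotypes are formed
    X_raw = X.copy()
    if spec.missing_rate > 0.0:
        mask = rng.random((n, q)) < spec.missing_rate
        X_raw[mask] = np.nan

    subject_ids = list(covariates.index)
    snp_names = [f"rs{j:06d}" for j in range(q)]
    pheno_names = [f"roi_{j:02d}" for j in range(p)]
    phenotypes = pd.DataFrame(Y, index=subject_ids, columns=pheno_names)
    genotypes_raw = pd.DataFrame(X_raw, index=subject_ids, columns=snp_names)
    dataset = Dataset(
        Y=Y,
        X=impute_median(X_raw, column_names=snp_names),
        Z=Z,
        phenotype_names=pheno_names,
        snp_names=snp_names,
        subject_ids=subject_ids,
        covariate_names=cov_names,
    )
    return SyntheticData(
        dataset=dataset,
        phenotypes=phenotypes,
        genotypes_raw=genotypes_raw,
        covariates=covariates,
        truth=GroundTruth(causal_indices=causal, weights=W, mafs=mafs),
    )


def _effect_scale(s: np.ndarray, u: np.ndarray, g2: float) -> float:
    """Positive c with Var(c s) / Var(c s + u) == g2 exactly (in-sample).

    Solves the quadratic c^2 v_s (1 - g2) - 2 c g2 cov(s, u) - g2 v_u = 0
    with empirical (ddof=0) moments.
    """
    v_s = float(np.var(s))
    v_u = float(np.var(u))
    cov = float(np.mean((s - s.mean()) * (u - u.mean())))
    a = v_s * (1.0 - g2)
    b = -2.0 * g2 * cov
    d = -g2 * v_u
    disc = b * b - 4.0 * a * d
    return (-b + np.sqrt(disc)) / (2.0 * a)


def write_files(data: SyntheticData, outdir: str, genotype_format: str = "tsv") -> dict[str, str]:
    """Write the cohort in the dialects the loader reads; returns the paths.

    ``genotype_format`` is ``"tsv"`` or ``"plink-raw"``.  A JSON sidecar
    records the planted ground truth.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    data.phenotypes.to_csv(paths["phenotypes"], sep="\t", index_label="subject_id")
    data.covariates.to_csv(paths["covariates"], sep="\t", index_label="subject_id")
    if genotype_format == "plink-raw":
        paths["genotypes"] = os.path.join(outdir, "genotypes.raw")
        ids = list(data.genotypes_raw.index)
        meta = pd.DataFrame(
            {"FID": ids, "IID": ids, "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9}
        )
        snps = data.genotypes_raw.reset_index(drop=True)
        snps.columns = [f"{c}_A" for c in snps.columns]
        pd.concat([meta, snps], axis=1).to_csv(
            paths["genotypes"], sep=" ", index=False, na_rep="NA"
        )
    elif genotype_format == "tsv":
        paths["genotypes"] = os.path.join(outdir, "genotypes.tsv")
        data.genotypes_raw.to_csv(
            paths["genotypes"], sep="\t", index_label="subject_id", na_rep="NA"
        )
    else:
        raise ConfigError(f"unknown genotype format {genotype_format!r}")
    truth = {
        "causal_indices": data.truth.causal_indices.tolist(),
        "causal_snps": [data.dataset.snp_names[j] for j in data.truth.causal_indices],
        "weights": data.truth.weights.tolist(),
        "mafs": data.truth.mafs.tolist(),
    }
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths
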