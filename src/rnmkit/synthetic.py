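"""Synthetic genotype/phenotype generator with known reaction-norm structure.

Emulates, at desk scale, a biobank-style design: biallelic SNP genotypes at
chosen minor-allele frequencies, a lifestyle covariate (continuous or
ordinal), a quantitative phenotype with additive genetic intercept/slope
effects and residual intercept/slope effects at chosen variance components,
nuisance fixed effects, and a liability-threshold prospective disease status.
Every draw is controlled by a single seed, and the generating ("truth")
quantities are retained so downstream estimators can be validated against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix
from .reml import VarianceComponents

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_covariate",
    "simulate_phenotype",
    "simulate_case_status",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``vc_true`` holds the six generative (co)variance parameters; the default
    plants moderate GxE and RxE interaction on top of equal additive genetic
    and residual intercept variances.  ``covariate_spec`` is
    ``("normal", {"mean": 0, "sd": 1})`` or ``("ordinal", {"n_levels": k})``
    (equiprobable levels, mimicking categorical lifestyle variables such as
    alcohol intake frequency or smoking status).  ``fixed_effects_spec`` lists
    (covariate_name, coefficient) pairs applied as nuisance fixed effects;
    the name "covariate" refers to the lifestyle covariate itself.
    """

    n_individuals: int = 1000
    n_snps: int = 500
    maf_range: tuple = (0.05, 0.5)
    vc_true: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(
            sigma2_a0=0.4, sigma2_a1=0.2, sigma2_t0=0.3, sigma2_t1=0.1
        )
    )
    covariate_spec: tuple = ("normal", None)
    fixed_effects_spec: list = field(default_factory=list)
    prevalence: float = 0.05
    liability_h2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        self.vc_true.validate(require_psd=True)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + salt)


@dataclass
class TruthRecord:
    """Per-individual generating quantities retained for recovery tests."""

    g0: np.ndarray  # genetic intercept value  sum_j w_ij a_j
    g1: np.ndarray  # genetic slope value      sum_j w_ij b_j
    e0: np.ndarray  # residual intercept
    e1: np.ndarray  # residual slope
    snp_effects: np.ndarray  # (m, 2) per-SNP (a_j, b_j)
    fixed_part: np.ndarray

    def risk(self, c: np.ndarray) -> np.ndarray:
        """True analogue of the predicted phenotype: g0 + (g1 + e1) * c."""
        return self.g0 + (self.g1 + self.e1) * c

    def to_frame(self, sample_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "IID": sample_ids,
                "g0": self.g0,
                "g1": self.g1,
                "e0": self.e0,
                "e1": self.e1,
            }
        )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw biallelic dosages: SNP j has allele frequency p_j ~ U(maf_range)
    and dosages ~ Binomial(2, p_j)."""
    rng = config.rng(salt=1)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_snps) if hi > lo else np.full(config.n_snps, lo)
    dosages = rng.binomial(2, p, size=(config.n_individuals, config.n_snps)).astype(float)
    sample_ids = [f"id{i + 1}" for i in range(config.n_individuals)]
    snp_ids = [f"snp{j + 1}" for j in range(config.n_snps)]
    return GenotypeMatrix(dosages=dosages, sample_ids=sample_ids, snp_ids=snp_ids)


def simulate_covariate(config: SimulationConfig) -> np.ndarray:
    """Draw the lifestyle covariate.

    Continuous ("normal") or ordinal with equiprobable integer levels
    0..k-1; ordinal values are returned as raw numeric codes and standardized
    downstream exactly like continuous ones.
    """
    rng = config.rng(salt=2)
    kind, params = config.covariate_spec
    n = config.n_individuals
    if kind == "normal":
        params = params or {}
        return rng.normal(params.get("mean", 0.0), params.get("sd", 1.0), size=n)
    if kind == "ordinal":
        params = params or {}
        k = int(params.get("n_levels", 3))
        probs = params.get("probs")
        if probs is None:
            probs = np.full(k, 1.0 / k)
        return rng.choice(np.arange(k, dtype=float), size=n, p=probs)
    raise ValueError(f"unknown covariate distribution: {kind!r}")


def _standardize_columns(dosages: np.ndarray) -> np.ndarray:
    """Center by 2p and scale by sqrt(2pq); monomorphic columns become zero
    (they carry no effect)."""
    p = dosages.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    W = np.zeros_like(dosages, dtype=float)
    ok = scale > 0
    W[:, ok] = (dosages[:, ok] - 2.0 * p[ok]) / scale[ok]
    return W


def simulate_phenotype(
    genotypes: GenotypeMatrix, covariate: np.ndarray, config: SimulationConfig
):
    """Generate y_i = sum_j w_ij (a_j + b_j c_i) + fixed + e0_i + e1_i c_i.

    Per-SNP effect pairs (a_j, b_j) are jointly normal with covariance equal
    to the genetic block of ``vc_true`` divided by m, so the total genetic
    variance is controlled by the block regardless of SNP count (matching the
    1/m scaling of the GRM).  Residual pairs come from the residual block.
    The covariate is standardized internally before entering the model.
    """
    covariate = np.asarray(covariate, dtype=float)
    n, m = genotypes.dosages.shape
    if covariate.shape != (n,):
        raise ValueError("genotype and covariate dimensions do not agree")
    rng = config.rng(salt=3)
    sd = covariate.std(ddof=1)
    c = (covariate - covariate.mean()) / sd if sd > 0 else np.zeros(n)

    W = _standardize_columns(genotypes.dosages)
    ab = _mvn_pairs(rng, config.vc_true.genetic_block / m, m)
    g0 = W @ ab[:, 0]
    g1 = W @ ab[:, 1]
    e = _mvn_pairs(rng, config.vc_true.residual_block, n)
    e0, e1 = e[:, 0], e[:, 1]

    fixed = np.zeros(n)
    for name, beta in config.fixed_effects_spec:
        if name == "covariate":
            fixed += beta * c
        else:
            raise ValueError(f"unknown fixed-effect covariate: {name!r}")

    y = g0 + g1 * c + fixed + e0 + e1 * c
    truth = TruthRecord(g0=g0, g1=g1, e0=e0, e1=e1, snp_effects=ab, fixed_part=fixed)
    return y, truth


def _mvn_pairs(rng, block, size):
    """Draw `size` iid bivariate normal pairs with 2x2 covariance `block`
    via its PSD square root (handles singular blocks, e.g. zero variances)."""
    vals, vecs = np.linalg.eigh(block)
    root = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T
    z = rng.standard_normal((size, 2))
    return z @ root.T


def simulate_case_status(
    truth: TruthRecord,
    covariate: np.ndarray,
    prevalence: float,
    seed: int,
    liability_h2: float = 0.5,
) -> np.ndarray:
    """Liability-threshold prospective case status.

    Liability = scaled true risk (genetic intercept + total interaction
    effects, i.e. g0 + (g1 + e1) c) + independent normal noise, with the risk
    explaining ``liability_h2`` of the liability variance.  Status is 1 for
    the top ``prevalence`` fraction of liability (empirical quantile), so the
    realized case count is round(prevalence * n).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    covariate = np.asarray(covariate, dtype=float)
    sd = covariate.std(ddof=1)
    c = (covariate - covariate.mean()) / sd if sd > 0 else np.zeros_like(covariate)
    risk = truth.risk(c)
    rsd = risk.std()
    if rsd > 0:
        liability = np.sqrt(liability_h2) * risk / rsd + rng.normal(
            0.0, np.sqrt(1.0 - liability_h2), size=risk.shape
        )
    else:
        liability = rng.normal(size=risk.shape)
    n = liability.shape[0]
    n_cases = int(round(prevalence * n))
    status = np.zeros(n, dtype=int)
    status[np.argsort(liability, kind="stable")[n - n_cases :]] = 1
    return status


def simulate_dataset(config: SimulationConfig):
    """Convenience bundle: genotypes, raw covariate, phenotype, truth, status."""
    g = simulate_genotypes(config)
    cov = simulate_covariate(config)
    y, truth = simulate_phenotype(g, cov, config)
    status = simulate_case_status(
        truth, cov, config.prevalence, seed=config.seed + 4,
        liability_h2=config.liability_h2,
    )
    return {
        "genotypes": g,
        "covariate": cov,
        "phenotype": y,
        "truth": truth,
        "status": status,
    }


def write_bundle(dataset, config: SimulationConfig, outdir):
    """Write a simulated dataset as PLINK bed/bim/fam plus TSV sidecars.

    The truth record is stored alongside the observables in the same bundle
    so tests never regenerate the two inconsistently.
    """
    import os

    from .plink import write_plink

    os.makedirs(outdir, exist_ok=True)
    g = dataset["genotypes"]
    prefix = os.path.join(outdir, "genotypes")
    write_plink(prefix, g)
    ids = g.sample_ids
    pd.DataFrame({"IID": ids, "value": dataset["covariate"]}).to_csv(
        os.path.join(outdir, "covariate.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"IID": ids, "value": dataset["phenotype"]}).to_csv(
        os.path.join(outdir, "phenotype.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"IID": ids, "status": dataset["status"]}).to_csv(
        os.path.join(outdir, "status.tsv"), sep="\t", index=False
    )
    dataset["truth"].to_frame(ids).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False
    )
    return prefix
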