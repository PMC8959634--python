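"""Genotype quality control, GRM construction and sample handling.

SNP-level filters (MAF, Hardy-Weinberg, call rate, duplicates), the
standardized genomic relationship matrix K = W W' / m, greedy relatedness
pruning, principal-component population-outlier removal, and the near-equal
random sample split used to keep per-group computation tractable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "QcReport",
    "filter_snps",
    "compute_grm",
    "prune_related",
    "pc_outlier_removal",
    "split_samples",
]


@dataclass
class GenotypeMatrix:
    """n x m allele dosages in {0, 1, 2} with NaN marking missing calls."""

    dosages: np.ndarray
    sample_ids: list
    snp_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lists do not match dosage dimensions")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (NaN)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele, missing-aware."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        sids, vids = self.sample_ids, self.snp_ids
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            sids = [self.sample_ids[i] for i in sample_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            d = d[:, snp_idx]
            vids = [self.snp_ids[j] for j in snp_idx]
        return GenotypeMatrix(dosages=d.copy(), sample_ids=sids, snp_ids=vids)


@dataclass
class GRM:
    """Genomic relationship matrix: covariance kernel of genetic effects."""

    values: np.ndarray
    sample_ids: list
    n_snps_used: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample ids do not match GRM dimension")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "GRM":
        idx = np.asarray(idx)
        return GRM(
            values=self.values[np.ix_(idx, idx)].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            n_snps_used=self.n_snps_used,
        )


@dataclass
class QcReport:
    """Per-rule exclusion counts from one filter_snps pass."""

    n_input: int = 0
    n_duplicate: int = 0
    n_call_rate: int = 0
    n_maf: int = 0
    n_hwe: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def hwe_chi2_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Hardy-Weinberg 1-df chi-square p per SNP: observed genotype counts
    (0/1/2) against n*(q^2, 2pq, p^2) at the sample allele frequency."""
    d = g.dosages
    pvals = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = d[:, j]
        col = col[~np.isnan(col)]
        n = col.size
        if n == 0:
            pvals[j] = 1.0
            continue
        obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()], float)
        p = col.sum() / (2 * n)
        q = 1.0 - p
        exp = n * np.array([q * q, 2 * p * q, p * p])
        mask = exp > 0
        if mask.sum() <= 1:  # monomorphic: HWE trivially holds
            pvals[j] = 1.0
            continue
        chi2 = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
        pvals[j] = float(stats.chi2.sf(chi2, df=1))
    return pvals


def filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-4,
    call_rate_min: float = 0.95,
):
    """Apply SNP-level QC: duplicates out, then call rate, MAF, and HWE.

    Returns the surviving GenotypeMatrix and a QcReport of per-rule exclusion
    counts.  Raises if nothing survives, naming the decisive rule.
    """
    for t, name in ((maf_min, "maf_min"), (hwe_p_min, "hwe_p_min"), (call_rate_min, "call_rate_min")):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    report = QcReport(n_input=g.n_snps)
    keep = np.ones(g.n_snps, dtype=bool)

    seen = set()
    for j, sid in enumerate(g.snp_ids):
        if sid in seen:
            keep[j] = False
            report.n_duplicate += 1
        seen.add(sid)

    call_rate = 1.0 - np.isnan(g.dosages).mean(axis=0)
    bad = keep & (call_rate < call_rate_min)
    report.n_call_rate = int(bad.sum())
    keep &= ~bad

    freq = g.allele_freqs
    maf = np.minimum(freq, 1.0 - freq)
    bad = keep & ~(maf >= maf_min)
    report.n_maf = int(bad.sum())
    keep &= ~bad

    hwe_p = hwe_chi2_pvalues(g)
    bad = keep & (hwe_p < hwe_p_min)
    report.n_hwe = int(bad.sum())
    keep &= ~bad

    report.n_kept = int(keep.sum())
    if report.n_kept == 0:
        counts = report.as_dict()
        rule = max(
            ("n_duplicate", "n_call_rate", "n_maf", "n_hwe"), key=lambda k: counts[k]
        )
        raise ValueError(f"no SNPs survive QC (largest exclusion: {rule})")
    logger.info("SNP QC: %s", report.as_dict())
    return g.subset(snp_idx=np.where(keep)[0]), report


def standardized_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing calls, then center each SNP by 2p and scale by
    sqrt(2pq).  Zero-variance SNPs must have been removed by filter_snps."""
    d = g.dosages.copy()
    p = g.allele_freqs
    if np.any(np.isnan(p)):
        raise ValueError("SNP with no observed calls; run filter_snps first")
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = 2.0 * p[nan_c]
    scale = np.sqrt(2.0 * p * (1.0 - p))
    if np.any(scale == 0):
        raise ValueError(
            "zero-variance SNP after standardization; run filter_snps first"
        )
    return (d - 2.0 * p) / scale


def compute_grm(g: GenotypeMatrix) -> GRM:
    """K = W W' / m over standardized dosages (GREML kernel).

    With many independent SNPs the diagonal averages to ~1 and off-diagonals
    shrink as 1/sqrt(m)."""
    W = standardized_dosages(g)
    m = g.n_snps
    K = (W @ W.T) / m
    return GRM(values=K, sample_ids=list(g.sample_ids), n_snps_used=m)


def prune_related(k: GRM, threshold: float = 0.05, seed: int = 0) -> list:
    """Remove one member of every pair with relatedness above `threshold`.

    Greedy over flagged pairs in descending relatedness; within a pair the
    removed member is chosen at random (seeded).  Iterates until no remaining
    off-diagonal exceeds the threshold.  Returns kept sample ids.
    """
    rng = np.random.default_rng(seed)
    K = k.values
    n = K.shape[0]
    iu = np.triu_indices(n, 1)
    vals = K[iu]
    order = np.argsort(-vals, kind="stable")
    removed = np.zeros(n, dtype=bool)
    for idx in order:
        if vals[idx] <= threshold:
            break
        i, j = iu[0][idx], iu[1][idx]
        if removed[i] or removed[j]:
            continue
        removed[i if rng.random() < 0.5 else j] = True
    return [k.sample_ids[i] for i in range(n) if not removed[i]]


def pc_outlier_removal(k: GRM, n_sd: float = 6.0) -> list:
    """Drop samples beyond +/- n_sd SDs on PC1 or PC2 of the GRM.

    PC scores are eigenvectors of K scaled by the square root of their
    eigenvalues.  Returns kept sample ids.
    """
    n = k.n
    if n < 3:
        raise ValueError("PC outlier removal needs at least 3 samples")
    vals, vecs = np.linalg.eigh(k.values)
    keep = np.ones(n, dtype=bool)
    if not np.isinf(n_sd):
        for comp in (n - 1, n - 2):  # top two eigenpairs
            score = vecs[:, comp] * np.sqrt(max(vals[comp], 0.0))
            sd = score.std(ddof=1)
            if sd == 0:
                continue
            keep &= np.abs(score - score.mean()) <= n_sd * sd
    return [k.sample_ids[i] for i in range(n) if keep[i]]


def split_samples(sample_ids, n_groups: int, seed: int = 0) -> dict:
    """Random near-equal partition into n_groups (sizes differ by <= 1).

    Returns {sample_id: group_index}; disjoint and exhaustive, deterministic
    under the seed.
    """
    n = len(sample_ids)
    if not 1 <= n_groups <= n:
        raise ValueError("n_groups must be between 1 and the number of samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = {}
    for g_idx, chunk in enumerate(np.array_split(perm, n_groups)):
        for i in chunk:
            assignment[sample_ids[int(i)]] = g_idx
    return assignment
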