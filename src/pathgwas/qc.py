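"""SNP and sample quality control, and stratification principal components.

SNP filters run in a fixed order -- autosome, call rate, minor allele
frequency, Hardy-Weinberg equilibrium in the pooled sample, then HWE within
each study site -- so the per-rule removal report is deterministic; the
retained set itself does not depend on the order. Sample QC removes low call
rate samples first, then heterozygosity outliers relative to the remaining
samples. PCs use the EIGENSTRAT normalization (centre by 2p, scale by
sqrt(p(1-p)), mean-impute missing genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA

from .io import AUTOSOMES, MISSING, GenotypeDataset

__all__ = [
    "QcThresholds",
    "hwe_test",
    "snp_qc",
    "sample_qc",
    "apply_qc",
    "compute_pcs",
]


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults follow common GWAS practice for array data."""

    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_combined_min: float = 1e-5
    hwe_p_per_study_min: float = 1e-4
    sample_call_rate_min: float = 0.95
    het_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("snp_call_rate_min", "maf_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("hwe_p_combined_min", "hwe_p_per_study_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    Expected genotype counts come from the observed allele frequency. A
    monomorphic SNP (one allele absent) returns p = 1 by convention.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    q = (2 * counts[2] + counts[1]) / (2 * n)  # frequency of the 'b' allele
    if q == 0.0 or q == 1.0:
        return 1.0
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorized HWE chi-square p per SNP column (missing excluded)."""
    obs = np.stack([(dosages == g).sum(axis=0) for g in (0, 1, 2)]).astype(float)
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (2 * obs[2] + obs[1]) / (2 * n)
        exp = n * np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        stat = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0).sum(axis=0)
        p = chi2.sf(stat, df=1)
    mono = (q == 0) | (q == 1) | (n == 0)
    return np.where(mono, 1.0, p)


def snp_qc(
    dataset: GenotypeDataset,
    thresholds: QcThresholds = QcThresholds(),
    per_study: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the SNP filters; return retained ids and a per-SNP report.

    The report records call rate, MAF, HWE p-values and, for each dropped SNP,
    the first failing rule in the fixed order autosome > call_rate > maf >
    hwe_combined > hwe_per_study. A SNP with zero non-missing calls fails the
    call-rate rule.
    """
    d = dataset.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / d.shape[0] if d.shape[0] else np.zeros(d.shape[1])

    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(observed, d, 0).sum(axis=0) / (2 * np.maximum(n_obs, 1))
    maf = np.where(n_obs > 0, np.minimum(alt, 1 - alt), 0.0)

    hwe_all = _hwe_pvalues(d)
    autosomal = dataset.snp_map["chrom"].isin(AUTOSOMES).to_numpy()

    fail_rule = np.array([""] * dataset.n_snps, dtype=object)
    fail_rule[(fail_rule == "") & ~autosomal] = "autosome"
    fail_rule[(fail_rule == "") & (call_rate < thresholds.snp_call_rate_min)] = "call_rate"
    fail_rule[(fail_rule == "") & (maf < thresholds.maf_min)] = "maf"
    fail_rule[(fail_rule == "") & (hwe_all < thresholds.hwe_p_combined_min)] = "hwe_combined"

    hwe_site_min = np.ones(dataset.n_snps)
    if per_study:
        sites = dataset.samples["site"].to_numpy()
        for site in pd.unique(sites):
            p_site = _hwe_pvalues(d[sites == site])
            hwe_site_min = np.minimum(hwe_site_min, p_site)
        fail_rule[(fail_rule == "") & (hwe_site_min < thresholds.hwe_p_per_study_min)] = (
            "hwe_per_study"
        )

    report = pd.DataFrame(
        {
            "snp_id": dataset.snp_map["snp_id"],
            "chrom": dataset.snp_map["chrom"],
            "pos": dataset.snp_map["pos"],
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p_combined": hwe_all,
            "hwe_p_per_study_min": hwe_site_min,
            "fail_rule": fail_rule,
            "retained": fail_rule == "",
        }
    )
    retained = report.loc[report["retained"], "snp_id"].tolist()
    return retained, report


def sample_qc(
    dataset: GenotypeDataset, thresholds: QcThresholds = QcThresholds()
) -> list[str]:
    """Return ids of samples passing call-rate and heterozygosity filters.

    Heterozygosity outliers are judged against the mean/SD of the samples that
    survive the call-rate filter; with zero spread nothing is removed.
    """
    d = dataset.dosages
    observed = d != MISSING
    n_obs = observed.sum(axis=1)
    call_rate = n_obs / d.shape[1] if d.shape[1] else np.ones(d.shape[0])
    keep = call_rate >= thresholds.sample_call_rate_min

    with np.errstate(invalid="ignore", divide="ignore"):
        het = (d == 1).sum(axis=1) / np.maximum(n_obs, 1)
    h = het[keep]
    if len(h) and np.isfinite(thresholds.het_outlier_sd):
        mu, sd = h.mean(), h.std()
        if sd > 0:
            keep &= np.abs(het - mu) <= thresholds.het_outlier_sd * sd
    return dataset.samples.loc[keep, "sample_id"].tolist()


def apply_qc(
    dataset: GenotypeDataset,
    thresholds: QcThresholds = QcThresholds(),
    per_study: bool = True,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Sample QC followed by SNP QC; returns the filtered dataset + SNP report."""
    sample_ids = sample_qc(dataset, thresholds)
    keep_rows = np.flatnonzero(dataset.samples["sample_id"].isin(sample_ids).to_numpy())
    ds = dataset.subset(sample_idx=keep_rows)
    retained, report = snp_qc(ds, thresholds, per_study=per_study)
    keep_cols = np.flatnonzero(ds.snp_map["snp_id"].isin(set(retained)).to_numpy())
    return ds.subset(snp_idx=keep_cols), report


def compute_pcs(dosages: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal component scores under EIGENSTRAT normalization.

    Missing dosages are mean-imputed per SNP; each SNP is centred by 2p and
    scaled by sqrt(p(1-p)) with p the observed allele frequency. Deterministic
    up to the sign of each component.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dosages, dtype=float)
    if k > min(d.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(d.shape)}")
    obs = d != MISSING
    n_obs = np.maximum(obs.sum(axis=0), 1)
    mean = np.where(obs, d, 0).sum(axis=0) / n_obs
    d = np.where(obs, d, mean[None, :])
    p = mean / 2
    scale = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    x = (d - mean[None, :]) / scale[None, :]
    solver = "full" if min(x.shape) <= 500 else "randomized"
    pca = PCA(n_components=k, svd_solver=solver, random_state=0)
    return pca.fit_transform(x)
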