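"""Per-SNP covariate-adjusted logistic association, batched for speed.

The pathway permutation null re-runs the whole genome scan once per shuffled
phenotype, so the per-SNP logistic fits are the hot loop of the entire
pipeline. :class:`BatchScanner` therefore solves all SNP models
simultaneously with a vectorized Newton/IRLS: the covariate block of every
Hessian is assembled from a shared matrix of covariate cross-products via
BLAS gemms, the per-SNP genotype border is added analytically, and all
(n x S) intermediates live in preallocated buffers so repeated scans do no
allocation. Missing genotypes enter as zero case-weights, which is exactly
per-SNP complete-case analysis.

Model per SNP: logit P(case) = b0 + covariates' g + beta * dosage, additive
0/1/2 genotype coding, Wald z = beta/SE, two-sided p, 95% CI =
exp(beta +/- 1.959964 SE). Fits that separate or fail to converge are
flagged (p set to 1) and excluded from gene scoring downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .io import MISSING, GenotypeDataset

__all__ = [
    "SnpAssociation",
    "snp_logistic",
    "association_scan",
    "logistic_scan",
    "scan_dataset",
    "build_covariates",
    "BatchScanner",
    "ScanResult",
]

_Z95 = 1.959964  # normal quantile used for the reported 95% CI
_ETA_CLIP = 35.0  # keeps expit off the overflow path while separation diverges
_BETA_DIVERGED = 15.0  # |log OR| beyond this is treated as separation


@dataclass(frozen=True)
class SnpAssociation:
    """Result of one per-SNP logistic fit."""

    snp_id: str
    beta: float
    or_: float
    ci95: tuple[float, float]
    wald_z: float
    p: float
    n_used: int
    converged: bool


@dataclass
class ScanResult:
    """Array view of a genome scan (aligned with the scanned SNP columns)."""

    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_used: np.ndarray
    converged: np.ndarray

    def to_associations(self) -> list[SnpAssociation]:
        out = []
        for i, sid in enumerate(self.snp_ids):
            b, s = float(self.beta[i]), float(self.se[i])
            out.append(
                SnpAssociation(
                    snp_id=sid,
                    beta=b,
                    or_=float(np.exp(b)),
                    ci95=(float(np.exp(b - _Z95 * s)), float(np.exp(b + _Z95 * s))),
                    wald_z=float(self.z[i]),
                    p=float(self.p[i]),
                    n_used=int(self.n_used[i]),
                    converged=bool(self.converged[i]),
                )
            )
        return out


def _fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Plain Newton fit for one design matrix (used as the warm start)."""
    beta = np.zeros(X.shape[1])
    ybar = min(max(y.mean(), 1e-12), 1 - 1e-12)
    beta[0] = np.log(ybar / (1 - ybar))
    for _ in range(max_iter):
        mu = expit(X @ beta)
        w = mu * (1 - mu)
        h = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


class BatchScanner:
    """Reusable engine fitting every SNP's adjusted model for many phenotypes.

    Construction converts the dosage matrix once (missingness mask, float
    genotypes, covariate cross-products) and allocates all iteration buffers;
    :meth:`scan` then fits one phenotype vector, so a permutation null of B
    shuffles costs B cheap calls.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        covariates: np.ndarray | None = None,
        dtype: np.dtype = np.float64,
    ):
        n, S = dosages.shape
        self.n, self.S = n, S
        self.dtype = np.dtype(dtype)
        Xc = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
        self.Xc = np.ascontiguousarray(Xc, dtype=dtype)
        self.k = self.Xc.shape[1]
        k = self.k

        self.M = (dosages != MISSING).astype(dtype)
        self.G = np.where(dosages == MISSING, 0, dosages).astype(dtype)
        self.n_used = self.M.sum(axis=0, dtype=np.float64).astype(int)

        # SNPs constant among their used samples can never be fit
        g_mean = self.G.sum(0) / np.maximum(self.n_used, 1)
        g_var = (self.G * self.G).sum(0) / np.maximum(self.n_used, 1) - g_mean**2
        self._nonconstant = g_var > 1e-12

        self.iu, self.ju = np.triu_indices(k)
        self.P = self.Xc[:, self.iu] * self.Xc[:, self.ju]

        # iteration buffers, reused across scans
        self._eta = np.empty((n, S), dtype=dtype)
        self._tmp = np.empty((n, S), dtype=dtype)
        self._mu = np.empty((n, S), dtype=dtype)
        self._W = np.empty((n, S), dtype=dtype)
        self._R = np.empty((n, S), dtype=dtype)
        self._grad = np.empty((S, k + 1))
        self._H = np.empty((S, k + 1, k + 1))
        self._B = np.empty((k + 1, S), dtype=dtype)

    def _hessian_gradient(self, y: np.ndarray, with_grad: bool) -> None:
        k = self.k
        Xc, G, M = self.Xc, self.G, self.M
        eta, tmp, mu, W, R = self._eta, self._tmp, self._mu, self._W, self._R

        np.matmul(Xc, self._B[:k], out=eta)
        np.multiply(G, self._B[k], out=tmp)
        eta += tmp
        np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
        expit(eta, out=mu)

        np.subtract(1.0, mu, out=W)
        W *= mu
        W *= M

        if with_grad:
            np.subtract(y[:, None], mu, out=R)
            R *= M
            self._grad[:, :k] = R.T @ Xc
            np.multiply(G, R, out=tmp)
            self._grad[:, k] = tmp.sum(axis=0, dtype=np.float64)

        H = self._H
        A = W.T @ self.P
        H[:, self.iu, self.ju] = A
        H[:, self.ju, self.iu] = A
        np.multiply(W, G, out=tmp)  # tmp = W*G
        cross = tmp.T @ Xc
        H[:, k, :k] = cross
        H[:, :k, k] = cross
        tmp *= G  # tmp = W*G^2
        H[:, k, k] = tmp.sum(axis=0, dtype=np.float64)

    def scan(self, status: np.ndarray, max_iter: int = 25, tol: float | None = None) -> ScanResult:
        if tol is None:
            tol = 1e-8 if self.dtype == np.float64 else 5e-4
        y = np.asarray(status, dtype=self.dtype)
        k, S = self.k, self.S

        cases_used = self.M.T.astype(np.float64) @ y.astype(np.float64)
        fitable = self._nonconstant & (cases_used > 0) & (cases_used < self.n_used)

        warm = _fit_logistic(self.Xc.astype(np.float64), y.astype(np.float64))
        B = self._B
        B[:k] = warm[:, None]
        B[k] = 0.0

        frozen = ~fitable  # never updated, reported non-converged
        settled = frozen.copy()  # frozen or converged
        singular = np.zeros(S, dtype=bool)
        for _ in range(max_iter):
            self._hessian_gradient(y, with_grad=True)
            self._grad[frozen] = 0.0
            self._H[frozen] = np.eye(k + 1)
            try:
                step = np.linalg.solve(self._H, self._grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                bad = ~(np.linalg.det(self._H) > 1e-12)
                singular |= bad & ~frozen
                frozen |= bad
                self._grad[frozen] = 0.0
                self._H[frozen] = np.eye(k + 1)
                step = np.linalg.solve(self._H, self._grad[..., None])[..., 0]
            B += step.T.astype(self.dtype)
            diverged = (np.abs(B[k]) > _BETA_DIVERGED) & ~frozen
            frozen |= diverged
            settled |= diverged | (np.abs(step).max(axis=1) < tol)
            if settled.all():
                break
        converged = settled & ~frozen

        # SE from the information at the final estimate
        se = np.full(S, np.nan)
        conv_idx = np.flatnonzero(converged)
        if len(conv_idx):
            self._hessian_gradient(y, with_grad=False)
            H = self._H[conv_idx]
            try:
                var = np.linalg.inv(H)[:, k, k]
            except np.linalg.LinAlgError:
                var = np.full(len(conv_idx), -1.0)
                for j, Hj in enumerate(H):
                    try:
                        var[j] = np.linalg.inv(Hj)[k, k]
                    except np.linalg.LinAlgError:
                        pass
            good = var > 0
            se[conv_idx[good]] = np.sqrt(var[good])
            converged[conv_idx[~good]] = False

        beta = B[k].astype(np.float64)
        with np.errstate(invalid="ignore"):
            z = np.where(converged, beta / se, 0.0)
        z = np.nan_to_num(z)
        p = np.where(converged, 2 * norm.sf(np.abs(z)), 1.0)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        beta = np.where(converged, beta, np.nan)
        return ScanResult(
            snp_ids=[],
            beta=beta,
            se=se,
            z=z,
            p=p,
            n_used=self.n_used.copy(),
            converged=converged,
        )


def logistic_scan(
    dosages: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> ScanResult:
    """One-shot scan: fit every dosage column against the phenotype.

    dosages: (n, S) with -1 for missing; status: (n,) 0/1; covariates (n, c)
    or None. For repeated scans of the same genotypes (permutations) build a
    :class:`BatchScanner` once instead.
    """
    return BatchScanner(dosages, covariates).scan(status, max_iter=max_iter, tol=tol)


def snp_logistic(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
) -> SnpAssociation:
    """Fit one SNP; missing dosages drop the sample for this SNP only."""
    res = logistic_scan(np.asarray(dosage).reshape(-1, 1), status, covariates)
    res.snp_ids = ["snp"]
    return res.to_associations()[0]


def association_scan(
    dataset: GenotypeDataset,
    retained_snps: list[str] | None = None,
    covariates: np.ndarray | None = None,
    status: np.ndarray | None = None,
) -> list[SnpAssociation]:
    """Map the per-SNP fit over the (QC-retained) SNPs of a dataset.

    ``status`` overrides the sample table's case-control labels, which lets
    the permutation machinery reuse the scan with shuffled labels. Per-SNP
    failures are flagged in the results, never raised.
    """
    return scan_dataset(dataset, retained_snps, covariates, status).to_associations()


def scan_dataset(
    dataset: GenotypeDataset,
    retained_snps: list[str] | None = None,
    covariates: np.ndarray | None = None,
    status: np.ndarray | None = None,
) -> ScanResult:
    """Array-level version of :func:`association_scan`."""
    ds = dataset if retained_snps is None else dataset.subset_snp_ids(retained_snps)
    y = ds.samples["status"].to_numpy() if status is None else np.asarray(status)
    res = logistic_scan(ds.dosages, y, covariates)
    res.snp_ids = ds.snp_map["snp_id"].tolist()
    return res


def build_covariates(
    samples, pcs: np.ndarray | None = None, include_site: bool = False
) -> np.ndarray:
    """Assemble the adjustment matrix: age, gender, pack-years [, PCs][, site].

    Site enters as 0/1 indicator columns (first site label is the reference),
    used when two studies are pooled into a combined analysis.
    """
    cols = [
        samples["age"].to_numpy(float),
        samples["gender"].to_numpy(float),
        samples["pack_years"].to_numpy(float),
    ]
    if pcs is not None:
        cols.extend(np.asarray(pcs, dtype=float).T)
    if include_site:
        labels = samples["site"].to_numpy()
        uniq = list(dict.fromkeys(labels))
        for lab in uniq[1:]:
            cols.append((labels == lab).astype(float))
    return np.column_stack(cols)
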