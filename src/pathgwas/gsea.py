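"""Weighted KS-like pathway enrichment with a phenotype-permutation null.

Genes, ranked by the squared Wald statistic of their representative SNP, are
walked from top to bottom; member genes of a pathway push a running sum up by
|r|^weight / N_R (N_R the sum of member weights) and non-members pull it down
by 1/(N - N_H). The enrichment score ES is the maximum value the running sum
attains (signed-maximum convention; the maximum-absolute-deviation variant is
available behind a flag). The null is built by shuffling case-control labels
-- covariates stay attached to their samples, genotypes untouched, principal
components are not recomputed -- and re-running the whole scan -> gene score
-> ES chain, which preserves gene size and intra-gene SNP correlation.

NES standardizes ES by its own pathway's permutation mean and SD; the
permutation p is one-sided toward enrichment with add-one smoothing,
p = (1 + #{perm ES >= observed}) / (B + 1). FDR follows the GSEA convention:
the tail fraction of all pathway-standardized permuted NES over the tail
fraction of observed NES, clipped at 1; pathways with negative NES get FDR 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import BatchScanner, ScanResult, logistic_scan
from .io import GenotypeDataset
from .mapping import PathwayGeneSet

__all__ = [
    "enrichment_score",
    "permutation_null",
    "normalize_and_test",
    "normalize_permutations",
    "compute_fdr",
    "run_enrichment",
    "EnrichmentRun",
    "PathwayResult",
]


@dataclass(frozen=True)
class PathwayResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    fdr: float


@dataclass
class EnrichmentRun:
    """Everything NES/p/FDR derive from, kept for audit and testing."""

    ranked_genes: list[str]
    r_values: np.ndarray
    memberships: dict[str, np.ndarray]  # pathway -> bool indicator over ranked_genes
    es_observed: dict[str, float]
    es_perm: np.ndarray  # (n_pathways, B)
    B: int
    seed: int


def enrichment_score(
    r_values: np.ndarray,
    member: np.ndarray,
    weight_exp: float = 1.0,
    convention: str = "signed_max",
) -> float:
    """ES of one gene set against a ranked list.

    r_values must be sorted non-increasing (the ranking statistics, all
    non-negative here); member marks the set's genes along that ranking.
    """
    r = np.asarray(r_values, dtype=float)
    m = np.asarray(member, dtype=bool)
    n = len(r)
    if n < 2:
        raise ValueError("ranked list must have at least 2 genes")
    if len(m) != n:
        raise ValueError("member indicator must align with r_values")
    if np.any(np.diff(r) > 1e-12):
        raise ValueError("r_values must be sorted non-increasing")
    n_h = int(m.sum())
    if not 1 <= n_h < n:
        raise ValueError("member set must be nonempty and a strict subset")
    es = _es_columns(r, m[:, None], weight_exp, convention)
    if np.isnan(es[0]):
        raise ValueError("degenerate ranking: all member statistics are zero")
    return float(es[0])


def _es_columns(
    r_sorted: np.ndarray,
    memb: np.ndarray,
    weight_exp: float,
    convention: str,
) -> np.ndarray:
    """Vectorized ES for many pathways (columns of the indicator matrix).

    Columns whose member weights sum to zero, or that are empty/full, come
    back NaN; callers decide whether that is an error or a dropped column.
    """
    if convention not in ("signed_max", "max_abs"):
        raise ValueError("convention must be 'signed_max' or 'max_abs'")
    n = len(r_sorted)
    w = np.abs(r_sorted) ** weight_exp
    hit = np.where(memb, w[:, None], 0.0)
    n_r = hit.sum(axis=0)
    n_h = memb.sum(axis=0)
    bad = (n_r <= 0) | (n_h == 0) | (n_h >= n)
    n_r_safe = np.where(bad, 1.0, n_r)
    miss_step = 1.0 / np.where(n_h >= n, 1, n - n_h)
    steps = hit / n_r_safe - np.where(memb, 0.0, miss_step)
    run = np.cumsum(steps, axis=0)
    if convention == "signed_max":
        es = run.max(axis=0)
    else:
        es = run[np.abs(run).argmax(axis=0), np.arange(run.shape[1])]
    return np.where(bad, np.nan, es)


@dataclass
class _EnrichmentContext:
    """Precomputed structure for repeated scan -> rank -> ES evaluation."""

    snp_cols: np.ndarray  # dosage columns used by the scans (mapped SNPs)
    flat_snp: np.ndarray  # per-gene SNP positions into snp_cols, concatenated
    gene_ptr: np.ndarray  # segment starts into flat_snp
    gene_ids: list[str]
    memb: np.ndarray  # (n_genes, n_pathways) bool
    pathway_names: list[str]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _build_context(
    dataset: GenotypeDataset,
    mapping: Mapping[str, Sequence[str]],
    pathway_sets: Sequence[PathwayGeneSet],
) -> _EnrichmentContext:
    snp_index = {sid: i for i, sid in enumerate(dataset.snp_map["snp_id"])}
    pos = dataset.snp_map["pos"].to_numpy()

    per_gene: dict[str, list[str]] = {}
    for sid, genes in mapping.items():
        for gid in genes:
            per_gene.setdefault(gid, []).append(sid)
    gene_ids = sorted(per_gene)

    used_cols = sorted({snp_index[sid] for sids in per_gene.values() for sid in sids})
    col_of = {c: i for i, c in enumerate(used_cols)}

    flat: list[int] = []
    ptr = [0]
    for gid in gene_ids:
        sids = per_gene[gid]
        # representative-SNP tie-break order: position, then id
        sids.sort(key=lambda s: (pos[snp_index[s]], s))
        flat.extend(col_of[snp_index[s]] for s in sids)
        ptr.append(len(flat))

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    memb = np.zeros((len(gene_ids), len(pathway_sets)), dtype=bool)
    for j, ps in enumerate(pathway_sets):
        for g in ps.genes:
            if g in gene_pos:
                memb[gene_pos[g], j] = True

    return _EnrichmentContext(
        snp_cols=np.array(used_cols, dtype=int),
        flat_snp=np.array(flat, dtype=int),
        gene_ptr=np.array(ptr[:-1], dtype=int),
        gene_ids=gene_ids,
        memb=memb,
        pathway_names=[p.name for p in pathway_sets],
    )


def _gene_stats(ctx: _EnrichmentContext, scan: ScanResult) -> np.ndarray:
    """Per-gene ranking statistic r = max squared Wald z over assigned SNPs.

    The maximum of z^2 picks the same SNP as the minimum two-sided Wald p, so
    this is the representative-SNP statistic. Flagged SNPs count -inf; a gene
    with no usable SNP comes back -inf and is dropped for that scan.
    """
    z2 = np.where(scan.converged, scan.z**2, -np.inf)
    vals = z2[ctx.flat_snp]
    return np.maximum.reduceat(vals, ctx.gene_ptr)


def _es_from_scan(
    ctx: _EnrichmentContext,
    scan: ScanResult,
    weight_exp: float,
    convention: str,
) -> np.ndarray:
    r = _gene_stats(ctx, scan)
    valid = np.isfinite(r)
    order = np.argsort(-r[valid], kind="stable")
    return _es_columns(r[valid][order], ctx.memb[valid][order], weight_exp, convention)


def permutation_null(
    dataset: GenotypeDataset,
    retained_snps: list[str] | None,
    covariates: np.ndarray | None,
    mapping: Mapping[str, Sequence[str]],
    pathway_sets: Sequence[PathwayGeneSet],
    B: int,
    seed: int,
    weight_exp: float = 1.0,
    convention: str = "signed_max",
) -> np.ndarray:
    """(n_pathways, B) ES matrix under shuffled case-control labels.

    Each permutation shuffles only the status vector (covariates stay with
    their samples) and repeats the association scan, gene scoring and ES
    computation for every pathway. Seeded and reproducible.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ds = dataset if retained_snps is None else dataset.subset_snp_ids(retained_snps)
    ctx = _build_context(ds, mapping, pathway_sets)
    # float32 engine: permutation ES only needs ~1e-4 precision on z, and the
    # halved memory traffic roughly doubles throughput of the B scans
    scanner = BatchScanner(ds.dosages[:, ctx.snp_cols], covariates, dtype=np.float32)
    y = ds.samples["status"].to_numpy()
    rng = np.random.default_rng(seed)
    out = np.empty((len(pathway_sets), B))
    for b in range(B):
        perm = rng.permutation(y)
        out[:, b] = _es_from_scan(ctx, scanner.scan(perm), weight_exp, convention)
    return out


def normalize_and_test(
    es_observed: np.ndarray, es_perm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """NES and one-sided permutation p per pathway.

    NES_k = (ES_k - mean_b ES_perm[k,b]) / sd_b; p_k = (1 + #{b: ES_perm[k,b]
    >= ES_k}) / (B_k + 1), counting only finite permutation entries. A pathway
    whose permutation distribution has no spread gets NES/p = NaN (flagged).
    """
    es_observed = np.asarray(es_observed, dtype=float)
    finite = np.isfinite(es_perm)
    n_b = finite.sum(axis=1)
    if (n_b < 2).any():
        raise ValueError("need >= 2 finite permutation ES per pathway")
    mean = np.nanmean(np.where(finite, es_perm, np.nan), axis=1)
    sd = np.nanstd(np.where(finite, es_perm, np.nan), axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nes = (es_observed - mean) / sd
    # ES is bounded by 1, so an SD at rounding scale means a degenerate null
    nes = np.where(sd > 1e-12, nes, np.nan)
    exceed = np.where(finite, es_perm >= es_observed[:, None], False).sum(axis=1)
    p = (1.0 + exceed) / (n_b + 1.0)
    return nes, p


def normalize_permutations(es_perm: np.ndarray) -> np.ndarray:
    """Standardize each permuted ES by its own pathway's permutation mean/SD."""
    finite = np.isfinite(es_perm)
    masked = np.where(finite, es_perm, np.nan)
    mean = np.nanmean(masked, axis=1, keepdims=True)
    sd = np.nanstd(masked, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (es_perm - mean) / sd


def compute_fdr(nes_observed: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """GSEA-convention FDR in the enrichment (positive NES) direction.

    FDR_k = [fraction of all permuted NES >= NES_k] / [fraction of observed
    NES >= NES_k], clipped at 1. Negative-NES pathways get FDR 1.
    """
    nes_observed = np.asarray(nes_observed, dtype=float)
    pool = nes_perm[np.isfinite(nes_perm)]
    obs = nes_observed[np.isfinite(nes_observed)]
    fdr = np.ones_like(nes_observed)
    for k, nes in enumerate(nes_observed):
        if not np.isfinite(nes) or nes < 0:
            continue
        num = (pool >= nes).mean() if len(pool) else 0.0
        den = (obs >= nes).mean()  # counts itself, never zero
        fdr[k] = min(1.0, num / den)
    return fdr


def run_enrichment(
    dataset: GenotypeDataset,
    covariates: np.ndarray | None,
    mapping: Mapping[str, Sequence[str]],
    pathway_sets: Sequence[PathwayGeneSet],
    B: int = 1000,
    seed: int = 0,
    weight_exp: float = 1.0,
    convention: str = "signed_max",
    observed_scan: ScanResult | None = None,
) -> tuple[pd.DataFrame, EnrichmentRun]:
    """Observed ES + permutation null + NES/p/FDR for every pathway set.

    ``observed_scan`` may pass in an already-computed genome scan (aligned
    with the dataset's SNPs) to avoid refitting. Returns the result table
    sorted by p and the full :class:`EnrichmentRun`.
    """
    if not pathway_sets:
        raise ValueError("no pathway sets to test (catalog empty after filtering)")
    ctx = _build_context(dataset, mapping, pathway_sets)
    G = dataset.dosages[:, ctx.snp_cols]
    y = dataset.samples["status"].to_numpy()

    if observed_scan is None:
        scan = logistic_scan(G, y, covariates)
    else:
        scan = ScanResult(
            snp_ids=[],
            beta=observed_scan.beta[ctx.snp_cols],
            se=observed_scan.se[ctx.snp_cols],
            z=observed_scan.z[ctx.snp_cols],
            p=observed_scan.p[ctx.snp_cols],
            n_used=observed_scan.n_used[ctx.snp_cols],
            converged=observed_scan.converged[ctx.snp_cols],
        )

    r = _gene_stats(ctx, scan)
    valid = np.isfinite(r)
    order = np.argsort(-r[valid], kind="stable")
    ranked_genes = [ctx.gene_ids[i] for i in np.flatnonzero(valid)[order]]
    r_sorted = r[valid][order]
    memb_sorted = ctx.memb[valid][order]
    es_obs = _es_columns(r_sorted, memb_sorted, weight_exp, convention)

    es_perm = permutation_null(
        dataset, None, covariates, mapping, pathway_sets, B, seed, weight_exp, convention
    )
    nes, p = normalize_and_test(es_obs, es_perm)
    fdr = compute_fdr(nes, normalize_permutations(es_perm))

    sizes = [int(memb_sorted[:, j].sum()) for j in range(len(pathway_sets))]
    table = pd.DataFrame(
        {
            "pathway": ctx.pathway_names,
            "size": sizes,
            "es": es_obs,
            "nes": nes,
            "p": p,
            "fdr": fdr,
        }
    ).sort_values("p", kind="stable", ignore_index=True)

    run = EnrichmentRun(
        ranked_genes=ranked_genes,
        r_values=r_sorted,
        memberships={
            name: memb_sorted[:, j] for j, name in enumerate(ctx.pathway_names)
        },
        es_observed=dict(zip(ctx.pathway_names, es_obs)),
        es_perm=es_perm,
        B=B,
        seed=seed,
    )
    return table, run
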