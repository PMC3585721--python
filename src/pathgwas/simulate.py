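"""Synthetic case-control GWAS generator with planted pathway enrichment.

The generator emulates the statistical structure a pathway-level GWAS analysis
assumes: biallelic autosomal SNPs at common allele frequencies, genes as
contiguous runs of 1-30 SNPs with intergenic gaps (including gaps that place
SNPs exactly at the mapping-window edge), pathways of configurable size with
configurable gene sharing between neighbours, optional two-subpopulation
stratification, and a logistic disease model with covariate effects plus
per-allele odds ratios planted in the member genes of "enriched" pathways.
Cases and controls are ascertained from a simulated source population, which
mirrors frequency-matched hospital-based sampling.

Linkage disequilibrium is not simulated: SNPs are independent given the
subpopulation. The phenotype-permutation null is LD-agnostic, so independence
suffices for exercising the pipeline; see the methods note for what this does
and does not validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .io import GenotypeDataset, GeneAnnotation, Pathway, PathwayCatalog
import pandas as pd

__all__ = [
    "SimulationConfig",
    "EnrichedPathway",
    "SimulationTruth",
    "simulate_dataset",
    "simulate_study_pair",
]


@dataclass(frozen=True)
class EnrichedPathway:
    """A pathway with planted association: which one, how much of it, how strong.

    pathway_index: position of the pathway in the generated catalog.
    causal_fraction: fraction of member genes that receive one causal SNP.
    odds_ratio: per-minor-allele odds ratio at each causal SNP.
    """

    pathway_index: int
    causal_fraction: float
    odds_ratio: float


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale case-control GWAS: balanced 500/500
    sampling from a ~10%-prevalence source population, 2,000 common SNPs
    (MAF 0.05-0.5) in 400 genes, 20 disjoint pathways of 10-20 genes, 1%
    genotype missingness, no stratification and no planted effects.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_snps: int = 2000
    n_genes: int = 400
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 20)
    maf_range: tuple[float, float] = (0.05, 0.5)
    stratification_delta: float = 0.0
    enriched_pathways: tuple[EnrichedPathway, ...] = ()
    covariate_effects: tuple[float, float, float] = (0.02, 0.40, 0.012)
    overlap_fraction: float = 0.0
    missing_rate: float = 0.01
    seed: int = 0
    # --- secondary knobs (rarely touched) ---
    site: str = "study1"
    baseline_prevalence: float = 0.10
    stratification_disease_effect: float = 0.40
    max_sampling_rounds: int = 50
    max_snps_per_gene: int = 30

    def __post_init__(self) -> None:
        eps = [
            e if isinstance(e, EnrichedPathway) else EnrichedPathway(*e)
            for e in self.enriched_pathways
        ]
        object.__setattr__(self, "enriched_pathways", tuple(eps))

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        smin, smax = self.pathway_size_range
        if not (1 <= smin <= smax <= self.n_genes):
            raise ValueError("pathway_size_range must lie within [1, n_genes]")
        for name in ("n_cases", "n_controls", "n_snps", "n_genes", "n_pathways"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_snps < self.n_genes:
            raise ValueError("n_snps must be >= n_genes (every gene holds a SNP)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.stratification_delta < 0:
            raise ValueError("stratification_delta must be >= 0")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        for e in self.enriched_pathways:
            if not 0 <= e.pathway_index < self.n_pathways:
                raise ValueError(f"enriched pathway index {e.pathway_index} out of range")
            if e.odds_ratio <= 0:
                raise ValueError("per-allele odds ratio must be > 0")
            if not 0 < e.causal_fraction <= 1:
                raise ValueError("causal_fraction must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth of the planted structure, for power/recovery checks."""

    enriched: np.ndarray  # (n_pathways,) bool
    causal_genes: dict[str, list[str]]  # pathway name -> planted member genes
    causal_snps: dict[str, float]  # snp_id -> per-allele log odds ratio


@dataclass
class _Genome:
    """Shared layout: SNP map, gene intervals, catalog, causal assignment."""

    snp_map: pd.DataFrame
    annotation: list[GeneAnnotation]
    catalog: PathwayCatalog
    truth: SimulationTruth
    maf: np.ndarray  # overall minor-allele frequency per SNP
    causal_idx: np.ndarray  # SNP column indices with planted effects
    causal_beta: np.ndarray  # aligned log odds ratios


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

_WINDOW_EDGE_BP = 50_000  # gaps are drawn so SNPs occur exactly at this offset


def _build_genome(config: SimulationConfig, rng: np.random.Generator) -> _Genome:
    n_genes, n_snps = config.n_genes, config.n_snps

    # SNPs per gene: 1..max_snps_per_gene, trimmed so the total fits n_snps
    # with ~10% of SNPs left intergenic.
    genic_target = max(n_genes, int(round(n_snps * 0.9)))
    hi = max(1, min(config.max_snps_per_gene, 2 * genic_target // n_genes))
    k = rng.integers(1, hi + 1, size=n_genes)
    excess = int(k.sum()) - genic_target
    while excess > 0:
        shrinkable = np.flatnonzero(k > 1)
        take = shrinkable[rng.integers(0, len(shrinkable))]
        k[take] -= 1
        excess -= 1
    n_intergenic = n_snps - int(k.sum())

    # genes round-robin over up to 22 autosomes
    n_chrom = min(22, n_genes)
    gene_chrom = np.arange(n_genes) % n_chrom + 1

    # distribute intergenic SNPs over the gaps that follow each gene
    inter_counts = rng.multinomial(n_intergenic, np.full(n_genes, 1 / n_genes))

    snp_chrom: list[int] = []
    snp_pos: list[int] = []
    snp_gene: list[int] = []  # -1 for intergenic
    gene_bounds: dict[int, tuple[int, int]] = {}
    cursor = {c: 10_000 for c in range(1, n_chrom + 1)}
    for g in range(n_genes):
        c = int(gene_chrom[g])
        pos = cursor[c] + int(rng.integers(5_000, 20_000))
        first = pos
        for j in range(int(k[g])):
            snp_chrom.append(c)
            snp_pos.append(pos)
            snp_gene.append(g)
            if j < k[g] - 1:
                pos += int(rng.integers(300, 3_000))
        margin_l = int(rng.integers(0, 500))
        margin_r = int(rng.integers(0, 500))
        gene_bounds[g] = (first - margin_l, pos + margin_r)
        gap_end = pos + margin_r + int(rng.integers(60_000, 160_000))
        # intergenic SNPs in the following gap; the first one sits exactly at
        # the window edge half the time so boundary cases occur in fixtures
        for j in range(int(inter_counts[g])):
            if j == 0 and rng.random() < 0.5 and gap_end - (pos + margin_r) > _WINDOW_EDGE_BP + 1_000:
                ipos = pos + margin_r + _WINDOW_EDGE_BP
            else:
                ipos = int(rng.integers(pos + margin_r + 1_000, gap_end))
            snp_chrom.append(c)
            snp_pos.append(ipos)
            snp_gene.append(-1)
        cursor[c] = gap_end

    order = np.lexsort((np.array(snp_pos), np.array(snp_chrom)))
    snp_chrom_a = np.array(snp_chrom)[order]
    snp_pos_a = np.array(snp_pos)[order]
    snp_gene_a = np.array(snp_gene)[order]

    letters = np.array(list("ACGT"))
    pair_idx = rng.integers(0, 4, size=(n_snps, 2))
    pair_idx[:, 1] = (pair_idx[:, 0] + 1 + pair_idx[:, 1] % 3) % 4  # distinct
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"rs{i:06d}" for i in range(n_snps)],
            "chrom": snp_chrom_a.astype(str),
            "pos": snp_pos_a,
            "allele1": letters[pair_idx[:, 0]],
            "allele2": letters[pair_idx[:, 1]],
        }
    )

    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    annotation = [
        GeneAnnotation(gene_ids[g], str(int(gene_chrom[g])), *gene_bounds[g])
        for g in range(n_genes)
    ]

    catalog = _build_catalog(config, rng, gene_ids)
    maf = rng.uniform(*config.maf_range, size=n_snps)
    truth, causal_idx, causal_beta = _plant_effects(
        config, rng, catalog, snp_map, snp_gene_a, gene_ids
    )
    return _Genome(snp_map, annotation, catalog, truth, maf, causal_idx, causal_beta)


def _build_catalog(
    config: SimulationConfig, rng: np.random.Generator, gene_ids: Sequence[str]
) -> PathwayCatalog:
    """Pathways of sizes drawn from the configured range; consecutive pathways
    share ``overlap_fraction`` of the smaller one's genes, all other pairs are
    disjoint (fresh genes are always drawn from the never-used pool)."""
    smin, smax = config.pathway_size_range
    unused = list(rng.permutation(len(gene_ids)))
    pathways: list[Pathway] = []
    prev: list[int] = []
    for p in range(config.n_pathways):
        size = int(rng.integers(smin, smax + 1))
        n_shared = int(round(config.overlap_fraction * min(size, len(prev))))
        shared = list(rng.choice(prev, size=n_shared, replace=False)) if n_shared else []
        n_fresh = size - len(shared)
        if n_fresh > len(unused):
            raise ValueError(
                "n_genes too small for the requested pathway sizes/overlap "
                f"(pathway {p} needs {n_fresh} fresh genes, {len(unused)} left)"
            )
        fresh = [unused.pop() for _ in range(n_fresh)]
        members = sorted(shared + fresh)
        pathways.append(
            Pathway(
                f"pw{p:03d}",
                f"synthetic pathway {p}",
                tuple(gene_ids[g] for g in members),
            )
        )
        prev = members
    return PathwayCatalog(pathways)


def _plant_effects(
    config: SimulationConfig,
    rng: np.random.Generator,
    catalog: PathwayCatalog,
    snp_map: pd.DataFrame,
    snp_gene: np.ndarray,
    gene_ids: Sequence[str],
) -> tuple[SimulationTruth, np.ndarray, np.ndarray]:
    enriched = np.zeros(config.n_pathways, dtype=bool)
    causal_genes: dict[str, list[str]] = {}
    causal_snps: dict[str, float] = {}
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}
    causal_idx: list[int] = []
    causal_beta: list[float] = []
    for spec in config.enriched_pathways:
        pw = catalog.pathways[spec.pathway_index]
        enriched[spec.pathway_index] = True
        n_causal = max(1, int(round(spec.causal_fraction * len(pw.genes))))
        chosen = rng.choice(len(pw.genes), size=n_causal, replace=False)
        genes = [pw.genes[i] for i in sorted(chosen)]
        causal_genes[pw.name] = genes
        beta = float(np.log(spec.odds_ratio))
        for gid in genes:
            snps_in_gene = np.flatnonzero(snp_gene == gene_pos[gid])
            j = int(snps_in_gene[rng.integers(0, len(snps_in_gene))])
            sid = snp_map["snp_id"].iloc[j]
            if sid not in causal_snps:
                causal_idx.append(j)
                causal_beta.append(beta)
            causal_snps[sid] = beta
    truth = SimulationTruth(enriched, causal_genes, causal_snps)
    return truth, np.array(causal_idx, dtype=int), np.array(causal_beta)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _subpop_freqs(maf: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    p1 = np.clip(maf - delta / 2, 0.01, 0.99)
    p2 = np.clip(maf + delta / 2, 0.01, 0.99)
    return p1, p2


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = np.clip(np.round(rng.normal(60, 8, size=n)), 30, 85)
    gender = (rng.random(n) < 0.7).astype(int)
    smoker = rng.random(n) < 0.5
    pack_years = np.where(smoker, rng.gamma(2.0, 12.0, size=n), 0.0)
    return pd.DataFrame({"age": age, "gender": gender, "pack_years": pack_years})


def _sample_cohort(
    config: SimulationConfig, genome: _Genome, rng: np.random.Generator
) -> GenotypeDataset:
    """Ascertain n_cases/n_controls from a simulated source population.

    Phenotypes depend only on the causal SNPs, covariates and subpopulation,
    so those are drawn for the full source pool; non-causal genotypes are
    drawn afterwards for the retained individuals only (exact, since given
    subpopulation they are independent of ascertainment).
    """
    n_need_case, n_need_ctrl = config.n_cases, config.n_controls
    b_age, b_gender, b_py = config.covariate_effects
    p1c, p2c = (f[genome.causal_idx] for f in _subpop_freqs(genome.maf, config.stratification_delta))
    beta = genome.causal_beta

    intercept = float(logit(config.baseline_prevalence))
    block = max(2_000, 2 * (n_need_case + n_need_ctrl))

    kept_cov: list[pd.DataFrame] = []
    kept_sub: list[np.ndarray] = []
    kept_causal: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    got_case = got_ctrl = 0
    for _ in range(config.max_sampling_rounds):
        sub = rng.random(block) < 0.5
        cov = _draw_covariates(rng, block)
        pmat = np.where(sub[:, None], p2c[None, :], p1c[None, :])
        g_causal = rng.binomial(2, pmat).astype(np.int8)
        eta = (
            intercept
            + b_age * (cov["age"].to_numpy() - 60.0)
            + b_gender * (cov["gender"].to_numpy() - 0.7)
            + b_py * (cov["pack_years"].to_numpy() - 12.0)
            + config.stratification_disease_effect * (sub - 0.5)
        )
        if len(beta):
            centered = g_causal - (p1c + p2c)[None, :]  # 2 * mean freq
            eta = eta + centered @ beta
        y = (rng.random(block) < expit(eta)).astype(int)

        take_case = np.flatnonzero(y == 1)[: n_need_case - got_case]
        take_ctrl = np.flatnonzero(y == 0)[: n_need_ctrl - got_ctrl]
        take = np.sort(np.concatenate([take_case, take_ctrl]))
        kept_cov.append(cov.iloc[take])
        kept_sub.append(sub[take])
        kept_causal.append(g_causal[take])
        kept_status.append(y[take])
        got_case += len(take_case)
        got_ctrl += len(take_ctrl)
        if got_case >= n_need_case and got_ctrl >= n_need_ctrl:
            break
    else:
        raise RuntimeError(
            f"could not ascertain {n_need_case} cases / {n_need_ctrl} controls "
            f"within {config.max_sampling_rounds} sampling rounds; "
            "check baseline_prevalence against the requested counts"
        )

    cov = pd.concat(kept_cov, ignore_index=True)
    sub = np.concatenate(kept_sub)
    g_causal = np.vstack(kept_causal)
    status = np.concatenate(kept_status)
    n = len(status)

    # non-causal genotypes given subpopulation, drawn in column blocks
    p1, p2 = _subpop_freqs(genome.maf, config.stratification_delta)
    dosages = np.empty((n, config.n_snps), dtype=np.int8)
    for lo in range(0, config.n_snps, 512):
        hi = min(lo + 512, config.n_snps)
        pmat = np.where(sub[:, None], p2[None, lo:hi], p1[None, lo:hi])
        dosages[:, lo:hi] = rng.binomial(2, pmat).astype(np.int8)
    dosages[:, genome.causal_idx] = g_causal

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = -1

    samples = pd.DataFrame(
        {
            "sample_id": [f"{config.site}_S{i:05d}" for i in range(n)],
            "status": status,
            "age": cov["age"].to_numpy(),
            "gender": cov["gender"].to_numpy(),
            "pack_years": cov["pack_years"].to_numpy(),
            "site": config.site,
        }
    )
    return GenotypeDataset(dosages=dosages, snp_map=genome.snp_map, samples=samples)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeDataset, list[GeneAnnotation], PathwayCatalog, SimulationTruth]:
    """Generate one synthetic study; identical config (incl. seed) gives
    bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = _build_genome(config, rng)
    dataset = _sample_cohort(config, genome, rng)
    return dataset, genome.annotation, genome.catalog, genome.truth


def simulate_study_pair(
    config: SimulationConfig,
    replication_cases: int,
    replication_controls: int,
    replication_site: str = "study2",
) -> tuple[
    GenotypeDataset,
    GenotypeDataset,
    list[GeneAnnotation],
    PathwayCatalog,
    SimulationTruth,
]:
    """Two cohorts sharing one genome, catalog and planted effects.

    Models a discovery/replication design: the same SNPs, genes, pathways and
    causal alleles underlie both studies, but samples are drawn independently.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genome = _build_genome(config, rng)
    discovery = _sample_cohort(config, genome, rng)
    rep_cfg = replace(
        config,
        n_cases=replication_cases,
        n_controls=replication_controls,
        site=replication_site,
    )
    replication = _sample_cohort(rep_cfg, genome, rng)
    return discovery, replication, genome.annotation, genome.catalog, genome.truth
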