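"""Discovery -> replication -> combined pathway analysis, plus sensitivity runs.

Stage 1 screens every pathway in the discovery study; pathways with
P <= 0.05 and FDR <= 0.50 are carried forward. Stage 2 declares a carried
pathway replicated when its replication-study P <= 0.05 (no FDR rule at this
stage). The combined analysis pools the two QC'd studies at the individual
level, re-applies SNP QC (pooled + per-site HWE), recomputes principal
components on the pooled genotypes and adds a study-site indicator covariate;
a replicated pathway is final when its combined P <= 0.05.

Sensitivity analyses rerun the whole pipeline with an alternate SNP-to-gene
window (reporting the concordance of discovery-significant sets as
100*|intersection|/|union|) or with named multi-pathway genes removed from
every pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import ScanResult, build_covariates, scan_dataset
from .gsea import EnrichmentRun, run_enrichment
from .io import GenotypeDataset, GeneAnnotation, PathwayCatalog, concat_datasets
from .mapping import (
    GeneScore,
    PathwayGeneSet,
    assign_snps_to_genes,
    build_pathway_sets,
    score_genes,
)
from .qc import QcThresholds, apply_qc, compute_pcs

__all__ = [
    "StagePlan",
    "GseaParams",
    "StageResult",
    "TwoStageReport",
    "analyze_study",
    "run_two_stage",
    "sensitivity_window",
    "sensitivity_remove_overlap_genes",
    "find_multi_pathway_genes",
]


@dataclass(frozen=True)
class StagePlan:
    """Selection thresholds of the two-stage design."""

    p_max: float = 0.05
    fdr_max: float = 0.50
    replication_p_max: float = 0.05
    combined_p_max: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_max", "fdr_max", "replication_p_max", "combined_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class GseaParams:
    """Knobs shared by every stage of a run."""

    window_bp: int = 50_000
    weight_exp: float = 1.0
    B: int = 1000
    n_pcs: int = 4
    size_min: int = 10
    size_max: int = 200
    convention: str = "signed_max"
    thresholds: QcThresholds = field(default_factory=QcThresholds)


@dataclass
class StageResult:
    """One study's full pipeline output."""

    table: pd.DataFrame  # pathway, size, es, nes, p, fdr (sorted by p)
    run: EnrichmentRun
    gene_scores: list[GeneScore]
    pathway_sets: list[PathwayGeneSet]
    dataset: GenotypeDataset  # post-QC
    scan: ScanResult
    mapping: Mapping[str, Sequence[str]]


@dataclass
class TwoStageReport:
    """Per-pathway NES/P across stages with selection flags.

    table columns: pathway, size, nes_disc, p_disc, fdr_disc, nes_rep, p_rep,
    nes_comb, p_comb, selected, replicated, final. Flags satisfy
    final => replicated => selected by construction.
    """

    table: pd.DataFrame
    discovery: StageResult
    replication: StageResult
    combined: StageResult
    plan: StagePlan


def analyze_study(
    dataset: GenotypeDataset,
    annotation: Sequence[GeneAnnotation],
    catalog: PathwayCatalog,
    params: GseaParams = GseaParams(),
    seed: int = 0,
    include_site: bool = False,
    qc_done: bool = False,
) -> StageResult:
    """QC -> PCs -> adjusted scan -> gene scores -> pathway enrichment."""
    if qc_done:
        ds = dataset
    else:
        ds, _ = apply_qc(dataset, params.thresholds, per_study=True)
    pcs = compute_pcs(ds.dosages, params.n_pcs)
    cov = build_covariates(ds.samples, pcs, include_site=include_site)
    scan = scan_dataset(ds, covariates=cov)

    mapping = assign_snps_to_genes(ds.snp_map, annotation, params.window_bp)
    gene_scores = score_genes(mapping, scan.to_associations(), ds.snp_map)
    pathway_sets = build_pathway_sets(
        catalog, gene_scores, params.size_min, params.size_max
    )
    table, run = run_enrichment(
        ds,
        cov,
        mapping,
        pathway_sets,
        B=params.B,
        seed=seed,
        weight_exp=params.weight_exp,
        convention=params.convention,
        observed_scan=scan,
    )
    return StageResult(table, run, gene_scores, pathway_sets, ds, scan, mapping)


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    # deterministic per-stage substreams so stage order never matters
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _apply_flags(table: pd.DataFrame, plan: StagePlan) -> pd.DataFrame:
    out = table.copy()
    out["selected"] = (out["p_disc"] <= plan.p_max) & (out["fdr_disc"] <= plan.fdr_max)
    out["replicated"] = out["selected"] & (out["p_rep"] <= plan.replication_p_max)
    out["final"] = out["replicated"] & (out["p_comb"] <= plan.combined_p_max)
    for col in ("selected", "replicated", "final"):
        out[col] = out[col].fillna(False).astype(bool)
    return out


def run_two_stage(
    discovery: GenotypeDataset,
    replication: GenotypeDataset,
    annotation: Sequence[GeneAnnotation],
    catalog: PathwayCatalog,
    plan: StagePlan = StagePlan(),
    params: GseaParams = GseaParams(),
    seed: int = 0,
) -> TwoStageReport:
    """Full two-stage analysis with a pooled combined stage.

    Both studies pass QC independently; the combined stage pools the QC'd
    studies on their common SNPs, re-filters SNPs with the per-site HWE rule
    active, recomputes PCs and adjusts for study site. An empty stage-1
    selection still yields a complete report.
    """
    s_disc, s_rep, s_comb = _stage_seeds(seed)
    disc = analyze_study(discovery, annotation, catalog, params, seed=s_disc)
    rep = analyze_study(replication, annotation, catalog, params, seed=s_rep)

    pooled = concat_datasets(disc.dataset, rep.dataset)
    pooled_qc, _ = apply_qc(pooled, params.thresholds, per_study=True)
    comb = analyze_study(
        pooled_qc,
        annotation,
        catalog,
        params,
        seed=s_comb,
        include_site=True,
        qc_done=True,
    )

    t = disc.table.rename(
        columns={"nes": "nes_disc", "p": "p_disc", "fdr": "fdr_disc", "es": "es_disc"}
    )[["pathway", "size", "es_disc", "nes_disc", "p_disc", "fdr_disc"]]
    t = t.merge(
        rep.table.rename(columns={"nes": "nes_rep", "p": "p_rep"})[
            ["pathway", "nes_rep", "p_rep"]
        ],
        on="pathway",
        how="left",
    )
    t = t.merge(
        comb.table.rename(columns={"nes": "nes_comb", "p": "p_comb"})[
            ["pathway", "nes_comb", "p_comb"]
        ],
        on="pathway",
        how="left",
    )
    table = _apply_flags(t, plan).sort_values("p_disc", kind="stable", ignore_index=True)
    return TwoStageReport(table, disc, rep, comb, plan)


def _significant_set(report: TwoStageReport) -> set[str]:
    t = report.table
    return set(t.loc[t["selected"], "pathway"])


def sensitivity_window(
    discovery: GenotypeDataset,
    replication: GenotypeDataset,
    annotation: Sequence[GeneAnnotation],
    catalog: PathwayCatalog,
    baseline_report: TwoStageReport | None = None,
    window_bp: int = 20_000,
    plan: StagePlan = StagePlan(),
    params: GseaParams = GseaParams(),
    seed: int = 0,
) -> tuple[TwoStageReport, float]:
    """Rerun the pipeline with an alternate SNP-to-gene window.

    Returns the alternate-window report and the concordance rate (percent)
    between the two windows' discovery-significant pathway sets, defined as
    100 * |intersection| / |union| (100 when both sets are empty).
    """
    if baseline_report is None:
        baseline_report = run_two_stage(
            discovery, replication, annotation, catalog, plan, params, seed
        )
    alt_params = GseaParams(
        window_bp=window_bp,
        weight_exp=params.weight_exp,
        B=params.B,
        n_pcs=params.n_pcs,
        size_min=params.size_min,
        size_max=params.size_max,
        convention=params.convention,
        thresholds=params.thresholds,
    )
    alt_report = run_two_stage(
        discovery, replication, annotation, catalog, plan, alt_params, seed
    )
    a, b = _significant_set(baseline_report), _significant_set(alt_report)
    union = a | b
    concordance = 100.0 if not union else 100.0 * len(a & b) / len(union)
    return alt_report, concordance


def sensitivity_remove_overlap_genes(
    discovery: GenotypeDataset,
    replication: GenotypeDataset,
    annotation: Sequence[GeneAnnotation],
    catalog: PathwayCatalog,
    genes_to_remove: Sequence[str],
    plan: StagePlan = StagePlan(),
    params: GseaParams = GseaParams(),
    seed: int = 0,
) -> TwoStageReport:
    """Rerun with the named genes stripped from every pathway's membership.

    Pathways that fall below the size minimum disappear from the report
    (they are "dropped"); everything else is recomputed from scratch.
    """
    if not len(genes_to_remove):
        raise ValueError("genes_to_remove must be nonempty")
    reduced = catalog.remove_genes(genes_to_remove)
    return run_two_stage(discovery, replication, annotation, reduced, plan, params, seed)


def find_multi_pathway_genes(
    pathway_sets: Sequence[PathwayGeneSet],
    gene_scores: Sequence[GeneScore],
    min_pathways: int = 3,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Genes in >= min_pathways pathways whose representative p <= p_max.

    Returns a table (gene_id, n_pathways, p_min, pathways) sorted by p; the
    usual use is flagging genes shared by more than two pathways for the
    gene-removal sensitivity analysis.
    """
    membership: dict[str, list[str]] = {}
    for ps in pathway_sets:
        for g in ps.genes:
            membership.setdefault(g, []).append(ps.name)
    rows = []
    for s in gene_scores:
        pws = membership.get(s.gene_id, [])
        if len(pws) >= min_pathways and s.p_min <= p_max:
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "n_pathways": len(pws),
                    "p_min": s.p_min,
                    "pathways": ",".join(sorted(pws)),
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_pathways", "p_min", "pathways"]
    ).sort_values(["p_min", "gene_id"], ignore_index=True)
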