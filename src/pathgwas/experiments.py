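"""Monte-Carlo calibration and power studies of the whole pipeline.

Each experiment simulates complete studies with the synthetic-data generator,
runs QC -> PCs -> adjusted scan -> mapping -> enrichment exactly as a real
analysis would, and summarizes operating characteristics: type-I error under
the global null, recovery of a planted pathway, two-stage flag behaviour and
the self-normalization of the permutation NES. Problem sizes default to
desk-scale values documented in the methods note; every replicate's seed
derives from the experiment seed.
"""

from __future__ import annotations

import numpy as np

from .gsea import normalize_and_test
from .simulate import SimulationConfig, simulate_dataset, simulate_study_pair
from .two_stage import GseaParams, analyze_study, run_two_stage

__all__ = [
    "type1_error_experiment",
    "power_experiment",
    "two_stage_experiment",
    "self_normalization_experiment",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def type1_error_experiment(
    n_datasets: int = 20,
    n_cases: int = 250,
    n_controls: int = 250,
    n_snps: int = 1000,
    n_genes: int = 650,
    n_pathways: int = 50,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Pathway p-values on global-null data; fraction at p <= 0.05.

    No planted effects and no stratification, so every pathway p should be
    uniform up to permutation granularity.
    """
    params = GseaParams(B=B, size_min=5, size_max=200)
    pvals: list[float] = []
    for s in _child_seeds(seed, n_datasets):
        cfg = SimulationConfig(
            n_cases=n_cases, n_controls=n_controls, n_snps=n_snps,
            n_genes=n_genes, n_pathways=n_pathways,
            pathway_size_range=(10, 12), seed=s,
        )
        ds, annotation, catalog, _ = simulate_dataset(cfg)
        stage = analyze_study(ds, annotation, catalog, params, seed=s + 1)
        pvals.extend(stage.table["p"].tolist())
    pvals_arr = np.array(pvals)
    return {
        "fraction_significant": float((pvals_arr <= 0.05).mean()),
        "n_pathway_tests": len(pvals_arr),
        "pvalues": pvals_arr,
    }


def power_experiment(
    n_replicates: int = 20,
    odds_ratio: float = 1.5,
    causal_fraction: float = 0.5,
    pathway_genes: int = 20,
    n_cases: int = 500,
    n_controls: int = 500,
    n_snps: int = 800,
    n_genes: int = 520,
    n_pathways: int = 25,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Recovery of one planted pathway: top NES and p <= 0.05 per replicate."""
    params = GseaParams(B=B)
    top, sig = [], []
    for s in _child_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            n_cases=n_cases, n_controls=n_controls, n_snps=n_snps,
            n_genes=n_genes, n_pathways=n_pathways,
            pathway_size_range=(pathway_genes, pathway_genes),
            enriched_pathways=[(0, causal_fraction, odds_ratio)], seed=s,
        )
        ds, annotation, catalog, truth = simulate_dataset(cfg)
        stage = analyze_study(ds, annotation, catalog, params, seed=s + 1)
        planted = catalog.pathways[0].name
        t = stage.table.set_index("pathway")
        top.append(t["nes"].idxmax() == planted)
        sig.append(bool(t.loc[planted, "p"] <= 0.05))
    top_arr, sig_arr = np.array(top), np.array(sig)
    return {
        "top_nes_rate": float(top_arr.mean()),
        "significant_rate": float(sig_arr.mean()),
        "success_rate": float((top_arr & sig_arr).mean()),
        "n_replicates": n_replicates,
    }


def two_stage_experiment(
    n_replicates: int = 10,
    odds_ratio: float = 1.4,
    causal_fraction: float = 0.5,
    discovery_n: tuple[int, int] = (500, 500),
    replication_n: tuple[int, int] = (400, 400),
    n_snps: int = 560,
    n_genes: int = 380,
    n_pathways: int = 20,
    size_range: tuple[int, int] = (12, 18),
    B: int = 200,
    seed: int = 0,
) -> dict:
    """Planted effect shared by both studies: selected/replicated/final rates.

    Also verifies the flag implications (final => replicated => selected) on
    every replicate's full report.
    """
    params = GseaParams(B=B)
    selected, replicated, final, implications = [], [], [], []
    for s in _child_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            n_cases=discovery_n[0], n_controls=discovery_n[1], n_snps=n_snps,
            n_genes=n_genes, n_pathways=n_pathways, pathway_size_range=size_range,
            enriched_pathways=[(0, causal_fraction, odds_ratio)], seed=s,
        )
        disc, rep, annotation, catalog, truth = simulate_study_pair(
            cfg, replication_n[0], replication_n[1]
        )
        rpt = run_two_stage(disc, rep, annotation, catalog, params=params, seed=s + 1)
        t = rpt.table
        implications.append(
            bool((t["replicated"] <= t["selected"]).all() and (t["final"] <= t["replicated"]).all())
        )
        planted = catalog.pathways[0].name
        row = t.set_index("pathway")
        if planted in row.index:
            selected.append(bool(row.loc[planted, "selected"]))
            replicated.append(bool(row.loc[planted, "replicated"]))
            final.append(bool(row.loc[planted, "final"]))
        else:  # planted pathway filtered out entirely: count as a miss
            selected.append(False)
            replicated.append(False)
            final.append(False)
    return {
        "selected_rate": float(np.mean(selected)),
        "replicated_rate": float(np.mean(replicated)),
        "final_rate": float(np.mean(final)),
        "implications_hold_rate": float(np.mean(implications)),
        "n_replicates": n_replicates,
    }


def self_normalization_experiment(
    B: int = 500,
    n_cases: int = 150,
    n_controls: int = 150,
    n_snps: int = 400,
    n_genes: int = 200,
    n_pathways: int = 10,
    seed: int = 0,
) -> dict:
    """Treat each permuted ES column as observed; the resulting NES must be
    standardized (mean ~ 0, SD ~ 1 across columns for every pathway)."""
    from .assoc import build_covariates
    from .gsea import permutation_null
    from .mapping import assign_snps_to_genes, build_pathway_sets, score_genes
    from .assoc import scan_dataset
    from .qc import apply_qc, compute_pcs

    cfg = SimulationConfig(
        n_cases=n_cases, n_controls=n_controls, n_snps=n_snps,
        n_genes=n_genes, n_pathways=n_pathways, pathway_size_range=(10, 14),
        seed=seed,
    )
    ds, annotation, catalog, _ = simulate_dataset(cfg)
    filt, _ = apply_qc(ds)
    cov = build_covariates(filt.samples, compute_pcs(filt.dosages, 4))
    mapping = assign_snps_to_genes(filt.snp_map, annotation, 50_000)
    scan = scan_dataset(filt, covariates=cov)
    scores = score_genes(mapping, scan.to_associations(), filt.snp_map)
    sets = build_pathway_sets(catalog, scores, size_min=5)
    es_perm = permutation_null(filt, None, cov, mapping, sets, B=B, seed=seed + 1)

    nes_cols = np.empty_like(es_perm)
    for b in range(es_perm.shape[1]):
        nes_cols[:, b], _ = normalize_and_test(es_perm[:, b], es_perm)
    means = nes_cols.mean(axis=1)
    sds = nes_cols.std(axis=1, ddof=1)
    return {
        "max_abs_mean": float(np.abs(means).max()),
        "sd_min": float(sds.min()),
        "sd_max": float(sds.max()),
        "n_pathways": es_perm.shape[0],
        "B": B,
    }
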