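"""Shared fixtures: hand-built QC datasets and small simulated studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pathgwas as pg

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_dataset(dosages, chroms=None, positions=None, site="study1", status=None):
    """Wrap a raw dosage matrix in a GenotypeDataset with plain covariates."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    if chroms is None:
        chroms = ["1"] * s
    if positions is None:
        positions = np.arange(1, s + 1) * 1000
    if status is None:
        status = np.array([1, 0] * (n // 2 + 1))[:n]
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j:03d}" for j in range(s)],
            "chrom": [str(c) for c in chroms],
            "pos": positions,
            "allele1": ["A"] * s,
            "allele2": ["G"] * s,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"i{i:03d}" for i in range(n)],
            "status": status,
            "age": np.full(n, 60.0),
            "gender": np.tile([0, 1], n // 2 + 1)[:n],
            "pack_years": np.zeros(n),
            "site": site,
        }
    )
    return pg.GenotypeDataset(dosages=dosages, snp_map=snp_map, samples=samples)


def qc_fixture_dataset():
    """20 samples x 10 SNPs with exactly 2 call-rate, 1 MAF and 1 HWE failures.

    SNPs 0-5 are clean (complete calls, MAF 0.3, near-equilibrium genotype
    counts 10/8/2). SNPs 6-7 have two missing calls each (call rate 0.90).
    SNP 8 carries one heterozygote (MAF 0.025). SNP 9 is all-heterozygous
    (HWE chi-square 20, p ~ 7.7e-6 < 1e-5). Six SNPs survive.
    """
    n = 20
    clean = np.array([0] * 10 + [1] * 8 + [2] * 2, dtype=np.int8)
    cols = []
    rng = np.random.default_rng(7)
    for _ in range(6):
        cols.append(rng.permutation(clean))
    for _ in range(2):  # call-rate failures: 18/20 called
        c = rng.permutation(clean).copy()
        c[:2] = -1
        cols.append(c)
    cols.append(np.array([0] * 19 + [1], dtype=np.int8))  # MAF 1/40
    cols.append(np.ones(n, dtype=np.int8))  # all het: HWE failure
    return make_dataset(np.column_stack(cols))


@pytest.fixture(scope="session")
def qc_dataset():
    return qc_fixture_dataset()


@pytest.fixture(scope="session")
def null_study():
    """Global-null study at the generator's default scale (no planted effects)."""
    cfg = pg.SimulationConfig(seed=101)
    ds, annotation, catalog, truth = pg.simulate_dataset(cfg)
    return ds, annotation, catalog, truth


@pytest.fixture(scope="session")
def planted_study():
    """Small study with one strongly enriched 20-gene pathway (OR 1.5)."""
    cfg = pg.SimulationConfig(
        n_cases=500,
        n_controls=500,
        n_snps=800,
        n_genes=420,
        n_pathways=20,
        pathway_size_range=(20, 20),
        enriched_pathways=[(0, 0.5, 1.5)],
        seed=11,
    )
    ds, annotation, catalog, truth = pg.simulate_dataset(cfg)
    return ds, annotation, catalog, truth


@pytest.fixture(scope="session")
def planted_stage(planted_study):
    """Full single-study pipeline output on the planted fixture (B=100)."""
    ds, annotation, catalog, _ = planted_study
    return pg.analyze_study(
        ds, annotation, catalog, pg.GseaParams(B=100), seed=5
    )
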