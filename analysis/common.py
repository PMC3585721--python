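"""Shared configuration of the demonstration analysis.

One synthetic two-centre case-control study pair with a single planted
pathway (OR 1.5 per causal allele on half the member genes), at a scale every
driver script finishes in well under a minute. Raw genotype text lives under
``scratch/``; small result tables under ``results/``.
"""

from pathlib import Path

import pathgwas as pg

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "demo_data"
RESULTS_DIR = ROOT / "results"

SEED = 2026
B_PERMUTATIONS = 200

STUDY = pg.SimulationConfig(
    n_cases=400,
    n_controls=400,
    n_snps=600,
    n_genes=320,
    n_pathways=20,
    pathway_size_range=(10, 18),
    stratification_delta=0.1,
    enriched_pathways=[(0, 0.5, 1.5)],
    missing_rate=0.01,
    seed=SEED,
)
REPLICATION_CASES = 300
REPLICATION_CONTROLS = 300

PARAMS = pg.GseaParams(B=B_PERMUTATIONS)


def load_pair():
    """Regenerate the study pair (bit-identical for a fixed SEED)."""
    return pg.simulate_study_pair(STUDY, REPLICATION_CASES, REPLICATION_CONTROLS)
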