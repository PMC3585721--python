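"""Two-stage orchestration: flags, pooling, sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pathgwas as pg
from pathgwas.mapping import PathwayGeneSet
from pathgwas.two_stage import _apply_flags, find_multi_pathway_genes


SMALL = dict(
    n_cases=250, n_controls=250, n_snps=400, n_genes=200, n_pathways=10,
    pathway_size_range=(12, 16), missing_rate=0.0,
    enriched_pathways=[(0, 0.6, 1.6)],
)


@pytest.fixture(scope="module")
def pair():
    cfg = pg.SimulationConfig(**SMALL, seed=33)
    return pg.simulate_study_pair(cfg, 200, 200)


@pytest.fixture(scope="module")
def report(pair):
    disc, rep, annotation, catalog, _ = pair
    return pg.run_two_stage(
        disc, rep, annotation, catalog, params=pg.GseaParams(B=60), seed=17
    )


def test_flag_implications_hold(report):
    t = report.table
    assert (t["replicated"] <= t["selected"]).all()
    assert (t["final"] <= t["replicated"]).all()


def test_planted_pathway_progresses_to_final(report, pair):
    truth = pair[4]
    name = pair[3].pathways[int(np.flatnonzero(truth.enriched)[0])].name
    row = report.table.set_index("pathway").loc[name]
    assert bool(row["selected"]) and bool(row["replicated"]) and bool(row["final"])


def test_combined_samples_equal_sum_of_stages(report):
    assert (
        report.combined.dataset.n_samples
        == report.discovery.dataset.n_samples + report.replication.dataset.n_samples
    )
    assert set(report.combined.dataset.samples["site"]) == {"study1", "study2"}


def test_relaxed_thresholds_select_everything(pair):
    disc, rep, annotation, catalog, _ = pair
    plan = pg.StagePlan(p_max=1.0, fdr_max=1.0, replication_p_max=1.0, combined_p_max=1.0)
    rpt = pg.run_two_stage(
        disc, rep, annotation, catalog, plan=plan, params=pg.GseaParams(B=20), seed=3
    )
    assert rpt.table["selected"].all()
    assert rpt.table["replicated"].all()
    assert rpt.table["final"].all()


def test_self_replication_consistency(pair):
    """Using the same dataset for both stages, a clear planted signal is both
    selected and replicated, and flag implications hold everywhere."""
    disc, _, annotation, catalog, truth = pair
    rpt = pg.run_two_stage(
        disc, disc, annotation, catalog, params=pg.GseaParams(B=60), seed=5
    )
    t = rpt.table.set_index("pathway")
    name = catalog.pathways[int(np.flatnonzero(truth.enriched)[0])].name
    assert bool(t.loc[name, "selected"]) and bool(t.loc[name, "replicated"])
    assert (rpt.table["replicated"] <= rpt.table["selected"]).all()


@given(st.data())
def test_apply_flags_implications_fuzz(data):
    n = data.draw(st.integers(min_value=1, max_value=12))
    f = lambda: [data.draw(st.floats(min_value=0.0, max_value=1.0)) for _ in range(n)]
    table = pd.DataFrame(
        {
            "pathway": [f"p{i}" for i in range(n)],
            "p_disc": f(), "fdr_disc": f(), "p_rep": f(), "p_comb": f(),
        }
    )
    out = _apply_flags(table, pg.StagePlan())
    assert (out["replicated"] <= out["selected"]).all()
    assert (out["final"] <= out["replicated"]).all()


def test_missing_stage_values_never_flag():
    table = pd.DataFrame(
        {
            "pathway": ["a"], "p_disc": [0.01], "fdr_disc": [0.1],
            "p_rep": [np.nan], "p_comb": [np.nan],
        }
    )
    out = _apply_flags(table, pg.StagePlan())
    assert bool(out["selected"][0]) and not bool(out["replicated"][0])


def test_sensitivity_window_self_comparison(pair, report):
    disc, rep, annotation, catalog, _ = pair
    _, concordance = pg.sensitivity_window(
        disc, rep, annotation, catalog,
        baseline_report=report, window_bp=50_000,
        params=pg.GseaParams(B=60), seed=17,
    )
    assert concordance == pytest.approx(100.0)


def test_sensitivity_window_alternate(pair, report):
    disc, rep, annotation, catalog, _ = pair
    alt, concordance = pg.sensitivity_window(
        disc, rep, annotation, catalog,
        baseline_report=report, window_bp=20_000,
        params=pg.GseaParams(B=60), seed=17,
    )
    assert 0.0 <= concordance <= 100.0
    assert alt.discovery.mapping != report.discovery.mapping


def test_remove_absent_gene_is_noop(pair, report):
    disc, rep, annotation, catalog, _ = pair
    alt = pg.sensitivity_remove_overlap_genes(
        disc, rep, annotation, catalog, ["NOT_A_GENE"],
        params=pg.GseaParams(B=60), seed=17,
    )
    pd.testing.assert_frame_equal(alt.table, report.table)


def test_remove_causal_genes_weakens_planted_pathway(pair, report):
    disc, rep, annotation, catalog, truth = pair
    name = catalog.pathways[int(np.flatnonzero(truth.enriched)[0])].name
    alt = pg.sensitivity_remove_overlap_genes(
        disc, rep, annotation, catalog, truth.causal_genes[name],
        params=pg.GseaParams(B=60), seed=17,
    )
    before = report.table.set_index("pathway").loc[name, "p_comb"]
    t_alt = alt.table.set_index("pathway")
    assert name not in t_alt.index or t_alt.loc[name, "p_comb"] > before


def test_remove_overlap_requires_genes():
    with pytest.raises(ValueError):
        pg.sensitivity_remove_overlap_genes(None, None, [], pg.PathwayCatalog([]), [])


def test_find_multi_pathway_genes_rules():
    sets = [
        PathwayGeneSet("p1", ("A", "B")),
        PathwayGeneSet("p2", ("A", "B", "C")),
        PathwayGeneSet("p3", ("A", "C")),
    ]
    scores = [
        pg.GeneScore("A", "s1", 0.005, 8.0, 3),  # 3 pathways, significant
        pg.GeneScore("B", "s2", 0.001, 10.0, 2),  # only 2 pathways
        pg.GeneScore("C", "s3", 0.5, 0.4, 1),  # 2 pathways and not significant
    ]
    out = find_multi_pathway_genes(sets, scores, min_pathways=3, p_max=0.01)
    assert out["gene_id"].tolist() == ["A"]
    assert out["pathways"].iloc[0] == "p1,p2,p3"
    assert out["n_pathways"].iloc[0] == 3


def test_find_multi_pathway_genes_on_fixture(report):
    out = find_multi_pathway_genes(
        report.discovery.pathway_sets, report.discovery.gene_scores,
        min_pathways=1, p_max=1.0,
    )
    member = {g for s in report.discovery.pathway_sets for g in s.genes}
    assert set(out["gene_id"]) == member & {s.gene_id for s in report.discovery.gene_scores}
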