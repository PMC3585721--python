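"""Window mapping, representative-SNP gene scores, pathway sets and overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import pathgwas as pg
from pathgwas.assoc import SnpAssociation
from pathgwas.io import Pathway
from pathgwas.mapping import (
    PathwayGeneSet,
    assign_snps_to_genes,
    build_pathway_sets,
    pathway_overlap,
    score_genes,
)


def snp_map_at(positions, chroms=None):
    chroms = chroms or ["1"] * len(positions)
    return pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(len(positions))],
            "chrom": chroms,
            "pos": positions,
            "allele1": "A",
            "allele2": "G",
        }
    )


def assoc(snp_id, p, z=None, converged=True):
    z = np.sqrt(-2 * np.log(p)) if z is None else z  # only ordering matters
    return SnpAssociation(
        snp_id=snp_id, beta=0.1, or_=1.1, ci95=(0.9, 1.3),
        wald_z=z, p=p, n_used=100, converged=converged,
    )


GENE = pg.GeneAnnotation("G", "1", 100_000, 120_000)


def test_window_boundary_inclusive_at_exact_distance():
    m = assign_snps_to_genes(snp_map_at([50_000, 49_999, 170_000, 170_001]), [GENE], 50_000)
    assert m == {"s0": ["G"], "s2": ["G"]}


def test_window_zero_keeps_only_intragenic():
    m = assign_snps_to_genes(snp_map_at([99_999, 100_000, 110_000, 120_000, 120_001]), [GENE], 0)
    assert sorted(m) == ["s1", "s2", "s3"]


def test_snp_in_overlapping_genes_maps_to_both():
    genes = [GENE, pg.GeneAnnotation("H", "1", 110_000, 130_000)]
    m = assign_snps_to_genes(snp_map_at([115_000]), genes, 0)
    assert sorted(m["s0"]) == ["G", "H"]


def test_other_chromosome_never_assigned():
    m = assign_snps_to_genes(snp_map_at([110_000], chroms=["2"]), [GENE], 50_000)
    assert m == {}


def test_empty_annotation_empty_mapping():
    assert assign_snps_to_genes(snp_map_at([1000]), [], 50_000) == {}


@given(st.integers(min_value=0, max_value=100_000), st.integers(min_value=0, max_value=100_000))
def test_window_monotonicity(w1, w2):
    w1, w2 = sorted((w1, w2))
    positions = list(range(10_000, 250_000, 7_000))
    small = assign_snps_to_genes(snp_map_at(positions), [GENE], w1)
    large = assign_snps_to_genes(snp_map_at(positions), [GENE], w2)
    assert set(small) <= set(large)


def test_score_genes_takes_minimum_p():
    mapping = {"s0": ["G"], "s1": ["G"], "s2": ["G"]}
    assocs = [assoc("s0", 0.04), assoc("s1", 0.002), assoc("s2", 0.5)]
    scores = score_genes(mapping, assocs, snp_map_at([1000, 2000, 3000]))
    assert len(scores) == 1
    s = scores[0]
    assert s.p_min == 0.002 and s.representative_snp == "s1" and s.n_snps == 3
    assert s.r == pytest.approx(assocs[1].wald_z ** 2)


def test_score_genes_position_tie_break():
    mapping = {"s0": ["G"], "s1": ["G"]}
    assocs = [assoc("s0", 0.01), assoc("s1", 0.01)]
    # s1 sits earlier on the chromosome -> wins the tie
    scores = score_genes(mapping, assocs, snp_map_at([5000, 1000]))
    assert scores[0].representative_snp == "s1"


def test_score_genes_skips_flagged_snps_and_drops_dead_genes():
    mapping = {"s0": ["G"], "s1": ["G"], "s2": ["H"]}
    assocs = [assoc("s0", 0.9), assoc("s1", 1e-5, converged=False), assoc("s2", 0.3, converged=False)]
    scores = score_genes(mapping, assocs, snp_map_at([1, 2, 3]))
    assert [s.gene_id for s in scores] == ["G"]
    assert scores[0].representative_snp == "s0"


def test_score_genes_hand_table():
    positions = [100, 200, 300, 400, 500, 600]
    mapping = {"s0": ["A"], "s1": ["A"], "s2": ["B"], "s3": ["C", "D"], "s4": ["D"], "s5": ["E"]}
    pvals = [0.5, 0.01, 0.2, 0.003, 0.4, 0.9]
    assocs = [assoc(f"s{i}", p) for i, p in enumerate(pvals)]
    scores = {s.gene_id: s for s in score_genes(mapping, assocs, snp_map_at(positions))}
    expected = {"A": 0.01, "B": 0.2, "C": 0.003, "D": 0.003, "E": 0.9}
    assert {g: s.p_min for g, s in scores.items()} == expected
    assert scores["D"].representative_snp == "s3"


@given(st.data())
def test_p_min_never_exceeds_any_member_p(data):
    n = data.draw(st.integers(min_value=1, max_value=8))
    pvals = [data.draw(st.floats(min_value=1e-6, max_value=1.0)) for _ in range(n)]
    mapping = {f"s{i}": ["G"] for i in range(n)}
    assocs = [assoc(f"s{i}", p) for i, p in enumerate(pvals)]
    scores = score_genes(mapping, assocs, snp_map_at(list(range(100, 100 + 100 * n, 100))))
    assert scores[0].p_min == min(pvals)


def _score(gene_ids):
    return [
        pg.GeneScore(g, "s", 0.5, 1.0, 1) for g in gene_ids
    ]


def test_build_pathway_sets_size_filter():
    catalog = pg.PathwayCatalog(
        [
            Pathway("tiny", "", tuple(f"g{i}" for i in range(5))),
            Pathway("minimal", "", tuple(f"g{i}" for i in range(10))),
            Pathway("mid", "", tuple(f"g{i}" for i in range(50))),
            Pathway("huge", "", tuple(f"g{i}" for i in range(250))),
        ]
    )
    scored = _score([f"g{i}" for i in range(250)])
    sets = build_pathway_sets(catalog, scored, size_min=10, size_max=200)
    assert [s.name for s in sets] == ["minimal", "mid"]


def test_build_pathway_sets_restricts_to_scored_genes():
    catalog = pg.PathwayCatalog([Pathway("p", "", tuple(f"g{i}" for i in range(12)))])
    scored = _score([f"g{i}" for i in range(9)])  # pathway shrinks below min
    assert build_pathway_sets(catalog, scored, size_min=10) == []
    with pytest.raises(ValueError):
        build_pathway_sets(catalog, [], size_min=10)


def test_boundary_sizes_inclusive():
    catalog = pg.PathwayCatalog(
        [
            Pathway("at200", "", tuple(f"g{i}" for i in range(200))),
            Pathway("at201", "", tuple(f"h{i}" for i in range(201))),
        ]
    )
    scored = _score([f"g{i}" for i in range(200)] + [f"h{i}" for i in range(201)])
    assert [s.name for s in build_pathway_sets(catalog, scored)] == ["at200"]


def test_pathway_overlap_worked_example():
    a = PathwayGeneSet("a", tuple(f"x{i}" for i in range(14)) + ("s1", "s2"))
    b = PathwayGeneSet("b", tuple(f"y{i}" for i in range(14)) + ("s1", "s2"))
    assert pathway_overlap(a, b) == pytest.approx(6.25)  # 100*2/32
    assert pathway_overlap(b, a) == pathway_overlap(a, b)


def test_pathway_overlap_bounds():
    a = PathwayGeneSet("a", tuple(f"x{i}" for i in range(10)))
    b = PathwayGeneSet("b", tuple(f"y{i}" for i in range(10)))
    assert pathway_overlap(a, b) == 0.0
    assert pathway_overlap(a, a) == 50.0  # maximum under the total-size rule
    assert pathway_overlap(a, b, denominator="union") == 0.0


@given(st.integers(0, 10), st.integers(1, 10), st.integers(1, 10))
def test_pathway_overlap_range_property(shared, extra_a, extra_b):
    a = PathwayGeneSet("a", tuple(f"s{i}" for i in range(shared)) + tuple(f"a{i}" for i in range(extra_a)))
    b = PathwayGeneSet("b", tuple(f"s{i}" for i in range(shared)) + tuple(f"b{i}" for i in range(extra_b)))
    v = pathway_overlap(a, b)
    assert 0.0 <= v <= 50.0
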