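"""Enrichment score, permutation null, NES/p and FDR."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pathgwas as pg
from pathgwas import gsea
from pathgwas.assoc import build_covariates, scan_dataset
from pathgwas.gsea import (
    compute_fdr,
    enrichment_score,
    normalize_and_test,
    normalize_permutations,
    permutation_null,
)


def es_bruteforce(r_values, member, weight_exp=1.0, convention="signed_max"):
    """Independent oracle: explicit walk over the ranked list."""
    n = len(r_values)
    n_h = sum(member)
    n_r = sum(abs(r) ** weight_exp for r, m in zip(r_values, member) if m)
    running, best, best_abs = 0.0, -np.inf, 0.0
    best_signed = None
    for r, m in zip(r_values, member):
        if m:
            running += abs(r) ** weight_exp / n_r
        else:
            running -= 1.0 / (n - n_h)
        best = max(best, running)
        if abs(running) >= best_abs + 1e-18:
            best_abs, best_signed = abs(running), running
    return best if convention == "signed_max" else best_signed


def test_single_member_ranked_first_gives_one():
    r = np.array([5.0, 3.0, 1.0])
    assert enrichment_score(r, np.array([True, False, False])) == pytest.approx(1.0)


def test_worked_running_sum_example():
    r = np.array([4.0, 3.0, 2.0, 1.0, 0.5])
    member = np.array([True, False, True, False, False])
    assert enrichment_score(r, member) == pytest.approx(2.0 / 3.0)


def test_members_at_bottom_give_nonpositive_es():
    r = np.array([9.0, 7.0, 5.0, 3.0, 1.0])
    member = np.array([False, False, False, True, True])
    assert enrichment_score(r, member) <= 1e-12


def test_es_error_cases():
    r = np.array([3.0, 2.0, 1.0])
    with pytest.raises(ValueError, match="sorted"):
        enrichment_score(np.array([1.0, 2.0, 3.0]), np.array([True, False, False]))
    with pytest.raises(ValueError, match="subset"):
        enrichment_score(r, np.array([True, True, True]))
    with pytest.raises(ValueError, match="subset"):
        enrichment_score(r, np.array([False, False, False]))
    with pytest.raises(ValueError, match="degenerate"):
        enrichment_score(np.array([1.0, 0.0, 0.0]), np.array([False, True, True]))


@given(st.data())
def test_es_matches_bruteforce_oracle(data):
    n = data.draw(st.integers(min_value=2, max_value=20))
    r = sorted(
        (data.draw(st.floats(min_value=0.0, max_value=50.0)) for _ in range(n)),
        reverse=True,
    )
    n_h = data.draw(st.integers(min_value=1, max_value=n - 1))
    member = np.zeros(n, dtype=bool)
    member[data.draw(st.permutations(list(range(n))))[:n_h]] = True
    w = data.draw(st.sampled_from([0.5, 1.0, 2.0]))
    if not any(r_i > 0 for r_i, m in zip(r, member) if m):
        return
    assert enrichment_score(np.array(r), member, w) == pytest.approx(
        es_bruteforce(r, member, w), abs=1e-12
    )


def test_normalize_and_test_basics():
    es_perm = np.array([[0.1, 0.3, 0.2, 0.4]])
    nes, p = normalize_and_test(np.array([es_perm.mean()]), es_perm)
    assert nes[0] == pytest.approx(0.0)
    # observed below the permutation mean -> negative NES
    nes_lo, _ = normalize_and_test(np.array([0.0]), es_perm)
    assert nes_lo[0] < 0


def test_permutation_p_floor_999():
    """Observed above all B=999 permuted values -> p exactly 1/1000."""
    rng = np.random.default_rng(0)
    es_perm = rng.uniform(-0.5, 0.5, size=(1, 999))
    nes, p = normalize_and_test(np.array([0.9]), es_perm)
    assert p[0] == pytest.approx(0.001, abs=0)
    assert nes[0] > 0


def test_p_counts_ties_and_smoothing():
    es_perm = np.array([[0.2, 0.5, 0.5, 0.1]])
    _, p = normalize_and_test(np.array([0.5]), es_perm)
    assert p[0] == pytest.approx((1 + 2) / 5)


def test_zero_spread_flagged():
    es_perm = np.full((1, 10), 0.3)
    nes, p = normalize_and_test(np.array([0.3]), es_perm)
    assert np.isnan(nes[0])


def test_fdr_top_pathway_zero():
    nes_obs = np.array([3.0, 1.0, 0.5])
    nes_perm = np.random.default_rng(1).normal(size=(3, 50))
    nes_perm = np.clip(nes_perm, None, 2.5)
    fdr = compute_fdr(nes_obs, nes_perm)
    assert fdr[0] == 0.0
    assert (fdr >= 0).all() and (fdr <= 1).all()


def test_fdr_negative_nes_is_one():
    fdr = compute_fdr(np.array([-0.5, 2.0]), np.zeros((2, 20)))
    assert fdr[0] == 1.0


def test_fdr_matches_hand_enumeration_small_grid():
    rng = np.random.default_rng(3)
    nes_obs = np.array([2.0, 0.5, -0.2])
    nes_perm = rng.normal(size=(3, 10))
    fdr = compute_fdr(nes_obs, nes_perm)
    pool = nes_perm.ravel()
    for k, v in enumerate(nes_obs):
        if v < 0:
            assert fdr[k] == 1.0
            continue
        num = (pool >= v).sum() / pool.size
        den = (nes_obs >= v).sum() / nes_obs.size
        assert fdr[k] == pytest.approx(min(1.0, num / den))


def test_exchangeable_observed_gives_fdr_near_one():
    rng = np.random.default_rng(4)
    nes_perm = rng.normal(size=(5, 200))
    nes_obs = nes_perm[:, 0]
    fdr = compute_fdr(nes_obs, nes_perm)
    assert (fdr[nes_obs > 0] > 0.3).all()


# ---------------------------------------------------------------------------
# permutation machinery on a real (small) dataset
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_run(planted_study):
    ds, annotation, catalog, _ = planted_study
    filt, _ = pg.apply_qc(ds)
    cov = build_covariates(filt.samples, pg.compute_pcs(filt.dosages, 4))
    mapping = pg.assign_snps_to_genes(filt.snp_map, annotation, 50_000)
    scan = scan_dataset(filt, covariates=cov)
    scores = pg.score_genes(mapping, scan.to_associations(), filt.snp_map)
    sets = pg.build_pathway_sets(catalog, scores)
    return filt, cov, mapping, sets, scan


def test_permutation_null_deterministic(small_run):
    ds, cov, mapping, sets, _ = small_run
    a = permutation_null(ds, None, cov, mapping, sets, B=3, seed=9)
    b = permutation_null(ds, None, cov, mapping, sets, B=3, seed=9)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (len(sets), 3)
    assert np.isfinite(a).all()


def test_identity_permutation_reproduces_observed_es(small_run):
    ds, cov, mapping, sets, scan = small_run
    table, run = pg.run_enrichment(ds, cov, mapping, sets, B=5, seed=1, observed_scan=scan)
    ctx = gsea._build_context(ds, mapping, sets)
    sub = gsea.ScanResult(
        snp_ids=[],
        beta=scan.beta[ctx.snp_cols], se=scan.se[ctx.snp_cols],
        z=scan.z[ctx.snp_cols], p=scan.p[ctx.snp_cols],
        n_used=scan.n_used[ctx.snp_cols], converged=scan.converged[ctx.snp_cols],
    )
    es_identity = gsea._es_from_scan(ctx, sub, 1.0, "signed_max")
    for j, name in enumerate(ctx.pathway_names):
        assert es_identity[j] == pytest.approx(run.es_observed[name], abs=1e-12)


def test_p_respects_permutation_granularity(small_run):
    ds, cov, mapping, sets, scan = small_run
    table, run = pg.run_enrichment(ds, cov, mapping, sets, B=19, seed=2, observed_scan=scan)
    assert (table["p"] >= 1 / 20 - 1e-12).all()
    assert table["p"].min() == pytest.approx(1 / 20)  # planted pathway hits the floor


def test_normalized_permutations_standardized(small_run):
    ds, cov, mapping, sets, _ = small_run
    es_perm = permutation_null(ds, None, cov, mapping, sets, B=40, seed=3)
    nes_perm = normalize_permutations(es_perm)
    np.testing.assert_allclose(nes_perm.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(nes_perm.std(axis=1, ddof=1), 1.0, atol=1e-10)


def test_run_enrichment_table_shape(small_run, planted_study):
    ds, cov, mapping, sets, scan = small_run
    table, run = pg.run_enrichment(ds, cov, mapping, sets, B=10, seed=4, observed_scan=scan)
    assert list(table.columns) == ["pathway", "size", "es", "nes", "p", "fdr"]
    assert len(table) == len(sets)
    assert table["p"].is_monotonic_increasing
    assert run.es_perm.shape == (len(sets), 10)
    # the planted pathway (pw000) tops the list on this fixture
    assert table["pathway"].iloc[0] == "pw000"
    sizes = {s.name: s.size for s in sets}
    assert all(int(r["size"]) == sizes[r["pathway"]] for _, r in table.iterrows())
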