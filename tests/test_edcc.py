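"""The EDCC decision engine: backgrounds, candidate calls, pairs, mutants."""

import numpy as np
import pytest

from crmscan.edcc import (
    INSUFFICIENT,
    build_background_model,
    build_backgrounds,
    count_pairs,
    decide,
    enumerate_pairs,
    evaluate_query,
    get_context,
    mutation_scan,
    quartile_dispersion_coefficient,
    random_cre,
    run_query_set,
    survivor_pwm,
)
from crmscan.expression import ExpressionCatalog, ZT_CATEGORIES, background_distribution
from crmscan.motifs import Motif, Query, parse_query
from crmscan.simulate import PlantSpec, generate_catalog, generate_promoters, plant


def test_random_cre_length_bounds_and_determinism():
    rng = np.random.default_rng(5)
    lengths = {len(random_cre(rng)) for _ in range(200)}
    assert lengths <= {5, 6, 7, 8}
    assert random_cre(np.random.default_rng(0)) == random_cre(np.random.default_rng(0))
    with pytest.raises(ValueError):
        random_cre(rng, 8, 5)


def test_random_cre_base_frequencies_uniform():
    rng = np.random.default_rng(11)
    bases = "".join(random_cre(rng) for _ in range(10_000))
    for b in "ACGT":
        assert abs(bases.count(b) / len(bases) - 0.25) < 0.02


@pytest.fixture(scope="module")
def single_cre(fixtures):
    return fixtures["single-cre"]


@pytest.fixture(scope="module")
def small_backgrounds(single_cre):
    rng = np.random.default_rng(21)
    return build_backgrounds(
        single_cre.promoters, single_cre.catalog, rng,
        n_backgrounds=30, n_random=50,
    )


def test_background_model_sd_positive_and_mean_near_background(single_cre):
    rng = np.random.default_rng(8)
    model = build_background_model(
        single_cre.promoters, single_cre.catalog, rng, n_random=100
    )
    assert (model.sd > 0).all()
    bg = background_distribution(single_cre.catalog).values
    # resampling property: the random-CRE mean DEM tracks the background
    assert (np.abs(model.mean - bg) <= 2.5 * model.sd / np.sqrt(100)).all()
    np.testing.assert_allclose(model.mean.sum(), 100, atol=1e-9)


def test_background_model_degenerate_catalog_has_zero_sd():
    rng = np.random.default_rng(2)
    promoters = generate_promoters(40, 300, rng=rng)
    catalog = ExpressionCatalog(
        ZT_CATEGORIES, {g: "ZT0-ZT4" for g in promoters.genes}
    )
    model = build_background_model(
        promoters, catalog, rng, n_random=20, min_matches=5
    )
    np.testing.assert_allclose(model.mean, [100, 0, 0, 0, 0, 0])
    np.testing.assert_allclose(model.sd, 0)


def test_background_model_draw_cap_errors():
    rng = np.random.default_rng(2)
    promoters = generate_promoters(10, 100, rng=rng)
    catalog = ExpressionCatalog(ZT_CATEGORIES, {g: "ZT0-ZT4" for g in promoters.genes})
    with pytest.raises(RuntimeError, match="qualifying"):
        build_background_model(
            promoters, catalog, rng, n_random=10, min_matches=11, max_draw_factor=2
        )


def test_planted_motif_called_candidate(single_cre, small_backgrounds):
    call = evaluate_query(
        single_cre.truth["planted"], single_cre.promoters, single_cre.catalog,
        backgrounds=small_backgrounds,
    )
    assert call.candidate
    assert call.votes > len(small_backgrounds) / 2
    assert single_cre.truth["target_category"] in call.flagged_categories


def test_query_matching_everything_is_not_candidate(single_cre, small_backgrounds):
    # "N" matches every promoter, so its DEM is exactly the background
    call = evaluate_query(
        "N", single_cre.promoters, single_cre.catalog, backgrounds=small_backgrounds
    )
    assert call.n_matching_promoters == len(single_cre.promoters)
    assert not call.candidate
    np.testing.assert_allclose(
        call.dem, background_distribution(single_cre.catalog).values
    )


def test_insufficient_occurrences_reason(single_cre, small_backgrounds):
    call = evaluate_query(
        single_cre.truth["planted"], single_cre.promoters, single_cre.catalog,
        backgrounds=small_backgrounds, min_matches=200,
    )
    assert not call.candidate
    assert call.reason == INSUFFICIENT


def test_candidate_count_monotone_in_threshold_and_min_matches(single_cre, small_backgrounds):
    ctx = get_context(single_cre.promoters, single_cre.catalog, "all")
    evals = []
    for q in single_cre.queries[:40]:
        n, d = ctx.query_dem(q)
        from crmscan.edcc import _deviations

        devs = None if d is None else _deviations(d, ctx.background, small_backgrounds)
        evals.append((q, n, d, devs))

    def count(threshold, min_matches):
        return sum(
            decide(q, n, d, devs, single_cre.catalog, threshold, min_matches,
                   len(small_backgrounds)).candidate
            for q, n, d, devs in evals
        )

    by_threshold = [count(t, 10) for t in (1, 2, 3, 4)]
    assert by_threshold == sorted(by_threshold, reverse=True)
    by_min = [count(1, m) for m in (10, 20, 30)]
    assert by_min == sorted(by_min, reverse=True)


def test_run_query_set_deterministic_and_reports(single_cre):
    queries = single_cre.queries[:10]

    def go():
        return run_query_set(
            queries, single_cre.promoters, single_cre.catalog,
            np.random.default_rng(77), n_repeats=3, n_backgrounds=10, n_random=30,
        )

    r1, r2 = go(), go()
    assert r1.candidate_sets == r2.candidate_sets
    assert r1.overlap == r2.overlap
    assert len(r1.counts) == 3
    single = run_query_set(
        queries, single_cre.promoters, single_cre.catalog,
        np.random.default_rng(1), n_repeats=1, n_backgrounds=5, n_random=20,
    )
    assert single.qdc is None


def test_qdc_formula():
    # linear-interpolation quartiles of [180..188 step 2]: Q1=182, Q3=186
    counts = [180, 182, 184, 186, 188]
    assert quartile_dispersion_coefficient(counts) == pytest.approx((186 - 182) / (186 + 182))
    assert quartile_dispersion_coefficient([5]) is None
    assert quartile_dispersion_coefficient([7, 7, 7]) == 0.0


def test_enumerate_pairs_counts_and_order():
    assert [q.label for q in enumerate_pairs(["A"])] == ["A,A"]
    pairs = enumerate_pairs(["C", "A", "G", "T", "A"])  # dedup to 4 motifs
    assert len(pairs) == 10 == count_pairs(["A", "C", "G", "T"])
    labels = [q.label for q in pairs]
    assert labels == sorted(labels)
    assert "A,A" in labels and "C,G" in labels


@pytest.fixture(scope="module")
def mutation_fixture():
    """Pair where all category signal enters through member A: B is a
    near-saturating 4-mer present almost everywhere."""
    rng = np.random.default_rng(31)
    promoters = generate_promoters(80, 300, rng=rng)
    spec = PlantSpec(
        ("GGATCCGTA",), n_target_promoters=30, position_model="uniform",
        target_category="ZT4-ZT8", rho=1.0,
    )
    promoters, manifest = plant(promoters, spec, rng)
    catalog = generate_catalog(
        promoters.genes, rng, planted_genes=manifest["gene_id"].unique(),
        target_category="ZT4-ZT8", rho=1.0,
    )
    return promoters, catalog


def test_mutation_scan_survivors_never_mutate_the_signal_member(mutation_fixture):
    promoters, catalog = mutation_fixture
    rng = np.random.default_rng(4)
    pair = Query((Motif("GGATCCGTA"), Motif("CATG")))
    result = mutation_scan(
        pair, promoters, catalog, rng, n_mutants=120, max_mutations=4,
        n_backgrounds=10, n_random=30, min_matches=15,
    )
    assert result.original.candidate
    assert all(m.n_mutations <= 4 for m in result.mutants)
    members = {m.members for m in result.mutants}
    assert len(members) == len(result.mutants)  # unique sampling
    zero = [m for m in result.mutants if m.n_mutations == 0]
    assert zero and all(m in result.survivors for m in zero)
    assert result.survivors
    for s in result.survivors:
        assert s.members[0] == "GGATCCGTA"  # signal member intact


def test_mutation_scan_space_cap_warns(mutation_fixture):
    promoters, catalog = mutation_fixture
    pair = Query((Motif("GGATCCGTA"), Motif("CATG")))
    with pytest.warns(UserWarning, match="capping"):
        result = mutation_scan(
            pair, promoters, catalog, np.random.default_rng(1),
            n_mutants=1000, max_mutations=1,
            n_backgrounds=2, n_random=10, min_matches=15,
        )
    assert len(result.mutants) == 1 + 13 * 3  # identity + single substitutions


def test_survivor_pwm_formula():
    freqs, importance = survivor_pwm("ACGT", ["ACGT", "ACGA"])
    np.testing.assert_allclose(importance, [1, 1, 1, 0.5])
    np.testing.assert_allclose(freqs.sum(axis=1), 1)
    # evenly split position has importance 0.25
    freqs2, imp2 = survivor_pwm("AAAA", ["AAAA", "CAAA", "GAAA", "TAAA"])
    assert imp2[0] == pytest.approx(0.25)
    with pytest.raises(ValueError):
        survivor_pwm("ACGT", [])


def test_pair_query_string_parsing_roundtrip():
    q = parse_query("CCACGTGGC,AGATATTT")
    assert q.is_pair and q.members[1].pattern == "AGATATTT"
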