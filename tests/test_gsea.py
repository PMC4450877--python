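"""Ranked-list construction, enrichment score, permutation null, FDR, screen."""

import numpy as np
import pytest

from prc2screen import (
    GeneSet,
    ParamConfig,
    RankedList,
    build_ranked_list,
    enrichment_score,
    fdr_q,
    leading_edge,
    pathway_screen,
    permutation_test,
)

from conftest import make_contrast


def equal_weight_list(n: int) -> RankedList:
    return RankedList([f"g{i}" for i in range(1, n + 1)], np.ones(n))


def es_bruteforce(weights, hit_mask, p_exp=1.0):
    """Direct-formula re-implementation, independent of the package code."""
    n = len(weights)
    n_hits = int(np.sum(hit_mask))
    denom = sum(abs(w) ** p_exp for w, h in zip(weights, hit_mask) if h)
    run, best = 0.0, 0.0
    for w, h in zip(weights, hit_mask):
        run += (abs(w) ** p_exp / denom) if h else (-1.0 / (n - n_hits))
        if abs(run) > abs(best) + 1e-12 or (
            abs(abs(run) - abs(best)) <= 1e-12 and run > 0 >= best
        ):
            best = run
    return best


class TestBuildRankedList:
    def test_filter_and_sort(self):
        con = make_contrast(
            ["a", "b", "c", "d"], m=[1.2, -0.5, 0.8, 0.3], p=[0.99, 0.95, 0.7, 0.4]
        )
        ranked = build_ranked_list(con, 0.5)
        assert ranked.genes == ["a", "c"]

    def test_equal_probability_ties_by_m(self):
        con = make_contrast(["a", "b"], m=[0.5, 2.0], p=[0.9, 0.9])
        assert build_ranked_list(con, 0.5).genes == ["b", "a"]

    def test_all_down_is_error(self):
        con = make_contrast(["a", "b"], m=[-1.0, -0.2], p=[0.99, 0.99])
        with pytest.raises(ValueError, match="empty ranked list"):
            build_ranked_list(con, 0.5)


class TestEnrichmentScore:
    def test_single_top_hit(self):
        es, _, peak = enrichment_score(equal_weight_list(4), GeneSet("s", "", ("g1",)))
        assert es == pytest.approx(1.0)
        assert peak == 0

    def test_single_bottom_hit(self):
        es, rs, peak = enrichment_score(equal_weight_list(4), GeneSet("s", "", ("g4",)))
        assert es == pytest.approx(-1.0)
        assert np.allclose(rs, [-1 / 3, -2 / 3, -1.0, 0.0])
        assert peak == 2

    def test_top_and_bottom_tie_prefers_positive(self):
        es, _, peak = enrichment_score(
            equal_weight_list(4), GeneSet("s", "", ("g1", "g4"))
        )
        assert es == pytest.approx(0.5)
        assert peak == 0

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            enrichment_score(equal_weight_list(3), GeneSet("s", "", ("zzz",)))

    def test_whole_list_convention(self):
        es, _, _ = enrichment_score(
            equal_weight_list(3), GeneSet("s", "", ("g1", "g2", "g3"))
        )
        assert es == 1.0

    def test_bounds_and_bruteforce_agreement(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(5, 51))
            k = int(rng.integers(1, n))
            w = np.sort(rng.random(n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            hits = np.zeros(n, dtype=bool)
            hits[rng.choice(n, k, replace=False)] = True
            ranked = RankedList(genes, w)
            gs = GeneSet("s", "", tuple(np.array(genes)[hits]))
            es, _, _ = enrichment_score(ranked, gs)
            assert -1.0 <= es <= 1.0
            assert es == pytest.approx(es_bruteforce(w, hits), abs=1e-10)

    def test_reversed_list_negates_shape(self):
        w = np.ones(6)
        genes = [f"g{i}" for i in range(6)]
        gs = GeneSet("s", "", ("g1", "g2"))
        _, rs_fwd, _ = enrichment_score(RankedList(genes, w), gs)
        _, rs_rev, _ = enrichment_score(RankedList(genes[::-1], w), gs)
        # the reversed walk mirrors the forward one: partial sums complement
        expected = np.append(-rs_fwd[::-1][1:], 0.0)
        assert np.allclose(rs_rev, expected, atol=1e-12)


class TestPermutationTest:
    def test_top_loaded_set_minimal_p(self):
        rng = np.random.default_rng(23)
        n = 2000
        w = np.sort(rng.uniform(0.5, 1.0, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = RankedList(genes, w)
        members = tuple(genes[:50])  # all members in the top 2.5%
        res = permutation_test(ranked, GeneSet("s", "", members), n_perm=999, seed=1)
        # no null subset reaches the observed ES: add-one numerator is exactly 1
        assert res.p == pytest.approx(1 / (1 + len(res.null_nes)))
        assert res.p < 2 / 1000
        assert res.nes > 1.0

    def test_same_seed_identical(self):
        ranked = equal_weight_list(50)
        gs = GeneSet("s", "", tuple(f"g{i}" for i in (1, 5, 9)))
        a = permutation_test(ranked, gs, n_perm=200, seed=3)
        b = permutation_test(ranked, gs, n_perm=200, seed=3)
        assert (a.p, a.nes) == (b.p, b.nes)

    def test_nominal_p_calibration_on_random_sets(self):
        """Type-I control: for random sets the p distribution is ~uniform."""
        from scipy import stats

        rng = np.random.default_rng(29)
        n = 1000
        w = np.sort(rng.uniform(0.5, 1.0, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = RankedList(genes, w)
        ps = []
        for _ in range(200):
            size = int(rng.integers(10, 40))
            members = tuple(np.array(genes)[rng.choice(n, size, replace=False)])
            res = permutation_test(
                ranked, GeneSet("r", "", members), n_perm=100,
                seed=int(rng.integers(2**31)),
            )
            ps.append(res.p)
        frac = np.mean([p < 0.05 for p in ps])
        # binomial 99% CI around 0.05 at 200 trials
        assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 200) + 1e-9
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_increases_with_top_loading(self):
        rng = np.random.default_rng(31)
        n = 500
        w = np.sort(rng.uniform(0.5, 1.0, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = RankedList(genes, w)
        ps = []
        for top_frac in (0.9, 0.5, 0.1):
            top = int(20 * top_frac)
            members = tuple(
                genes[:top] + list(np.array(genes)[rng.choice(np.arange(100, n), 20 - top, replace=False)])
            )
            res = permutation_test(ranked, GeneSet("s", "", members), n_perm=500, seed=7)
            ps.append(res.p)
        assert ps == sorted(ps)


class TestLeadingEdge:
    def test_positive_es_members_before_peak(self):
        ranked = equal_weight_list(4)
        gs = GeneSet("s", "", ("g1", "g4"))
        es, _, peak = enrichment_score(ranked, gs)
        assert leading_edge(ranked, gs, es, peak) == ["g1"]

    def test_set_entirely_before_peak(self):
        ranked = equal_weight_list(10)
        gs = GeneSet("s", "", ("g1", "g2", "g3"))
        es, _, peak = enrichment_score(ranked, gs)
        assert leading_edge(ranked, gs, es, peak) == ["g1", "g2", "g3"]

    def test_negative_es_members_after_peak(self):
        ranked = equal_weight_list(4)
        gs = GeneSet("s", "", ("g4",))
        es, _, peak = enrichment_score(ranked, gs)
        assert es < 0
        assert leading_edge(ranked, gs, es, peak) == ["g4"]


class TestFdr:
    def test_planted_set_q_near_zero_random_sets_high(self):
        rng = np.random.default_rng(37)
        n = 1000
        w = np.sort(rng.uniform(0.5, 1.0, n))[::-1]
        genes = [f"g{i}" for i in range(n)]
        ranked = RankedList(genes, w)
        sets = [GeneSet("planted", "", tuple(genes[:40]))]
        for i in range(10):
            members = tuple(np.array(genes)[rng.choice(n, 30, replace=False)])
            sets.append(GeneSet(f"rand{i}", "", members))
        results = [
            permutation_test(ranked, s, n_perm=200, seed=100 + i)
            for i, s in enumerate(sets)
        ]
        fdr_q(results)
        by_name = {r.set_name: r for r in results}
        assert by_name["planted"].q <= 0.01
        others = [r.q for r in results if r.set_name != "planted" and r.es > 0]
        assert np.median(others) > 0.2

    def test_identical_sets_identical_q(self):
        ranked = equal_weight_list(30)
        gs = GeneSet("a", "", tuple(f"g{i}" for i in range(1, 6)))
        gs2 = GeneSet("b", "", gs.members)
        r1 = permutation_test(ranked, gs, n_perm=100, seed=5)
        r2 = permutation_test(ranked, gs2, n_perm=100, seed=5)
        fdr_q([r1, r2])
        assert r1.q == r2.q

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fdr_q([])


class TestPathwayScreen:
    def test_planted_lines_detected(self):
        rng = np.random.default_rng(41)
        n = 600
        genes = [f"g{i}" for i in range(n)]
        focal = tuple(genes[:30])
        collection = [GeneSet("FOCAL", "", focal)]
        for i in range(5):
            members = tuple(np.array(genes)[rng.choice(n, 25, replace=False)])
            collection.append(GeneSet(f"D{i}", "", members))
        contrasts = {}
        for line, planted in (("L1", True), ("L2", True), ("L3", False)):
            p = rng.uniform(0.55, 0.8, n)
            m = rng.uniform(0.1, 1.0, n)
            if planted:
                p[:30] = rng.uniform(0.95, 1.0, 30)
            contrasts[line] = make_contrast(genes, list(m), list(p), cell_line=line)
        params = ParamConfig(n_perm=300)
        report = pathway_screen(contrasts, collection, params, focal_set="FOCAL",
                                master_seed=13)
        assert "FOCAL" in report.significant["L1"]
        assert "FOCAL" in report.significant["L2"]
        assert "FOCAL" not in report.significant["L3"]

    def test_empty_collection_empty_report(self):
        con = make_contrast(["a", "b"], [1.0, 0.5], [0.99, 0.8])
        report = pathway_screen({"L1": con}, [], ParamConfig(n_perm=50))
        assert report.enrichments["L1"] == []
        assert report.significant["L1"] == []

    def test_line_with_empty_ranking_recorded(self):
        good = make_contrast(["a", "b"], [1.0, 0.5], [0.99, 0.8], cell_line="L1")
        bad = make_contrast(["a", "b"], [-1.0, -0.5], [0.99, 0.8], cell_line="L2")
        gs = [GeneSet("S", "", ("a",))]
        report = pathway_screen({"L1": good, "L2": bad}, gs, ParamConfig(n_perm=50))
        assert report.skipped_lines == ["L2"]

    def test_focal_induced_matrix_matches_planted_flags(self):
        genes = ["a", "b", "c"]
        con = make_contrast(genes, [1.0, 1.0, 1.0], [0.99, 0.5, 0.95])
        gs = [GeneSet("S", "", ("a", "b", "c"))]
        report = pathway_screen({"L1": con}, gs, ParamConfig(n_perm=50),
                                focal_set="S")
        col = report.induced_matrix["L1"]
        assert bool(col["a"]) and bool(col["c"]) and not bool(col["b"])
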