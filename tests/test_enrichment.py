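import itertools

import numpy as np
import pytest
from scipy import stats

from pathprop import (GeneScoreVector, Pathway, PathwayCollection, bh_adjust,
                      ks_pathway_test, mw_pathway_test, permutation_test,
                      results_to_frame, run_cascade)
from pathprop.enrichment import child_seed

from conftest import collection_of, propagated_vector


def brute_force_bh(p):
    """Independent step-up implementation: sort, scale by n/rank, cummin."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestKsAndMw:
    def test_top_scores_pathway_is_extreme(self):
        v = propagated_vector(np.arange(100, dtype=float))
        top = {f"G{i}" for i in range(80, 100)}
        assert ks_pathway_test(v, top) < 1e-6
        assert mw_pathway_test(v, top) < 1e-6

    def test_bottom_scores_not_flagged_by_one_sided_greater(self):
        v = propagated_vector(np.arange(100, dtype=float))
        bottom = {f"G{i}" for i in range(20)}
        assert ks_pathway_test(v, bottom) > 0.5
        assert mw_pathway_test(v, bottom) > 0.5

    def test_value_for_value_duplicates_give_p_one(self):
        # pathway scores duplicate background values exactly: D = 0
        v = propagated_vector([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        members = {"G0", "G1", "G2"}
        assert ks_pathway_test(v, members) == 1.0

    def test_all_tied_scores_give_mw_p_one(self):
        v = propagated_vector([2.0] * 10)
        assert mw_pathway_test(v, {"G0", "G1", "G2"}) == 1.0

    def test_mw_exact_enumeration_top3_of_100(self):
        # pathway = the 3 largest of 100 distinct scores; the one-sided exact
        # p-value is 1 / C(100, 3), the chance of that most extreme split
        from math import comb
        v = propagated_vector(np.arange(100, dtype=float) + 1)
        p = mw_pathway_test(v, {"G97", "G98", "G99"})
        assert p == pytest.approx(1 / comb(100, 3), rel=1e-9)

    def test_small_pathway_rejected(self):
        v = propagated_vector([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ks_pathway_test(v, {"G0"})
        with pytest.raises(ValueError):
            mw_pathway_test(v, {"G0"})

    @pytest.mark.parametrize("test_fn", [ks_pathway_test, mw_pathway_test])
    def test_null_p_values_approximately_uniform(self, test_fn):
        # random pathway in an i.i.d. score universe: p ~ Uniform(0,1)
        ps = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            v = propagated_vector(rng.uniform(0, 1, 150))
            members = {f"G{i}" for i in rng.choice(150, 20, replace=False)}
            ps.append(test_fn(v, members))
        ks_to_uniform = stats.kstest(ps, "uniform").pvalue
        assert ks_to_uniform > 1e-3
        assert abs(np.mean(np.array(ps) <= 0.05) - 0.05) < 0.035


class TestPermutationTest:
    def test_top_pathway_attains_add_one_floor(self):
        rng = np.random.default_rng(5)
        v = propagated_vector(np.sort(rng.uniform(0, 1, 100)))
        top = {f"G{i}" for i in range(97, 100)}
        observed, p, null = permutation_test(v, top, n_perm=999, seed=1)
        assert observed == pytest.approx(v.scores[-3:].mean())
        # only a draw of exactly the top-3 set can tie the observed mean
        n_ties = int(np.sum(null.statistics >= observed))
        assert p == pytest.approx((1 + n_ties) / 1000)
        assert p <= 3 / 1000

    def test_constant_scores_give_p_one(self):
        v = propagated_vector([4.0] * 20)
        _, p, _ = permutation_test(v, {"G0", "G1"}, n_perm=500, seed=0)
        assert p == 1.0

    def test_empirical_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 1, 6)
        v = propagated_vector(values)
        members = {"G0", "G3"}
        observed, p_emp, _ = permutation_test(v, members, n_perm=10000, seed=3)
        exact_tail = sum(
            1 for pair in itertools.combinations(range(6), 2)
            if values[list(pair)].mean() >= observed
        )
        p_exact = exact_tail / 15
        se = np.sqrt(p_exact * (1 - p_exact) / 10000)
        assert abs(p_emp - p_exact) <= 3 * se + 2 / 10001

    def test_reproducible_under_fixed_seed(self):
        v = propagated_vector(np.random.default_rng(0).uniform(0, 1, 50))
        r1 = permutation_test(v, {"G1", "G2", "G3"}, n_perm=200, seed=42)
        r2 = permutation_test(v, {"G1", "G2", "G3"}, n_perm=200, seed=42)
        assert r1[0] == r2[0] and r1[1] == r2[1]
        assert np.array_equal(r1[2].statistics, r2[2].statistics)

    def test_p_strictly_positive_and_at_most_one(self):
        rng = np.random.default_rng(9)
        v = propagated_vector(rng.uniform(0, 1, 40))
        for seed in range(10):
            members = {f"G{i}" for i in
                       np.random.default_rng(seed).choice(40, 5, replace=False)}
            _, p, _ = permutation_test(v, members, n_perm=99, seed=seed)
            assert 0 < p <= 1


class TestBhAdjust:
    def test_hand_computed_example(self):
        # step-up: (0.01*3/1, 0.02*3/2, 0.03*3/3) -> cummin -> all 0.03
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.4, 0.4, 0.4]), 0.4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-15)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)


def planted_universe(seed=0, n=120, m=12):
    """Propagated-like universe with one clearly elevated pathway."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 1, n)
    signal = rng.choice(n, m, replace=False)
    values[signal] += 2.0
    v = propagated_vector(values)
    members = frozenset(f"G{i}" for i in signal)
    decoys = [frozenset(f"G{i}" for i in rng.choice(n, m, replace=False))
              for _ in range(9)]
    col = PathwayCollection(
        [Pathway("PLANTED", "", members)]
        + [Pathway(f"D{i}", "", d) for i, d in enumerate(decoys)]
    )
    return v, col


class TestRunCascade:
    def test_requires_propagated_scores(self):
        v = GeneScoreVector(["A", "B"], [1.0, 2.0], "raw")
        col = collection_of({"A", "B"})
        with pytest.raises(ValueError, match="propagated"):
            run_cascade(v, col)

    def test_planted_pathway_significant_and_rank_one(self):
        v, col = planted_universe()
        res = run_cascade(v, col, n_perm=2000, seed=0)
        assert res[0].pathway == "PLANTED"
        assert res[0].significant and res[0].rank == 1
        assert res[0].perm_p is not None

    def test_no_ks_survivor_means_no_later_stages(self):
        rng = np.random.default_rng(1)
        v = propagated_vector(rng.uniform(0, 1, 100))
        col = collection_of(*[{f"G{i}" for i in
                               np.random.default_rng(s).choice(100, 10, False)}
                              for s in range(5)])
        res = run_cascade(v, col, threshold=1e-6, n_perm=100, seed=0)
        assert all(r.mw_p is None and r.perm_p is None for r in res)
        assert not any(r.significant for r in res)

    def test_vacuous_threshold_reaches_all_stages(self):
        v, col = planted_universe(seed=2)
        res = run_cascade(v, col, threshold=1.0, n_perm=200, seed=0)
        assert all(r.mw_p is not None and r.perm_p is not None for r in res)

    def test_raising_threshold_never_removes_later_stage(self):
        v, col = planted_universe(seed=3)
        lo = run_cascade(v, col, threshold=0.05, n_perm=200, seed=0)
        hi = run_cascade(v, col, threshold=0.5, n_perm=200, seed=0)
        mw_lo = {r.pathway for r in lo if r.mw_p is not None}
        mw_hi = {r.pathway for r in hi if r.mw_p is not None}
        perm_lo = {r.pathway for r in lo if r.perm_p is not None}
        perm_hi = {r.pathway for r in hi if r.perm_p is not None}
        assert mw_lo <= mw_hi and perm_lo <= perm_hi

    def test_deterministic_and_order_independent(self):
        v, col = planted_universe(seed=4)
        res1 = run_cascade(v, col, n_perm=500, seed=7)
        res2 = run_cascade(v, col, n_perm=500, seed=7)
        shuffled = PathwayCollection(list(reversed(col.pathways)))
        res3 = run_cascade(v, shuffled, n_perm=500, seed=7)
        t1, t2, t3 = (results_to_frame(r).to_csv() for r in (res1, res2, res3))
        assert t1 == t2 == t3

    def test_ranks_are_a_permutation(self):
        v, col = planted_universe(seed=5)
        res = run_cascade(v, col, n_perm=200, seed=0)
        assert sorted(r.rank for r in res) == list(range(1, len(res) + 1))

    def test_small_pathways_skipped(self):
        v, _ = planted_universe(seed=6)
        col = collection_of({"G0"}, {f"G{i}" for i in range(10)})
        res = run_cascade(v, col, n_perm=100, seed=0)
        assert [r.pathway for r in res] == ["PW1"]

    def test_direction_from_raw_scores(self):
        v, col = planted_universe(seed=7)
        raw = GeneScoreVector(list(v.genes), -np.abs(v.scores), "raw")
        res = run_cascade(v, col, n_perm=100, seed=0, raw_scores=raw)
        assert all(r.direction == "down" for r in res)

    def test_frame_uses_na_for_missing_stages(self):
        rng = np.random.default_rng(8)
        v = propagated_vector(rng.uniform(0, 1, 100))
        col = collection_of(*[{f"G{i}" for i in
                               np.random.default_rng(s).choice(100, 10, False)}
                              for s in range(6)])
        res = run_cascade(v, col, threshold=1e-9, n_perm=100, seed=0)
        frame = results_to_frame(res)
        assert frame["mw_p"].isna().all()
        assert list(frame.columns)[:3] == ["pathway", "effective_size",
                                           "direction"]


class TestChildSeed:
    def test_stable_and_in_range(self):
        s = child_seed(123, "PATHWAY_X")
        assert s == child_seed(123, "PATHWAY_X")
        assert 0 <= s < 2**31

    def test_distinct_across_names_and_masters(self):
        assert child_seed(1, "A") != child_seed(1, "B")
        assert child_seed(1, "A") != child_seed(2, "A")
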