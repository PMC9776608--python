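import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from prostnet import (
    GeneSet,
    RankedList,
    bh_adjust,
    build_ranked_list,
    deg_filter,
    gsea_es,
    gsea_permutation,
    ora_hypergeom,
    rank_statistic,
    ranksum_test,
    set_activity_scores,
)


def brute_force_es(stats_in_order, member_flags, weight=1.0):
    """Independent running-sum evaluation by explicit loop."""
    N = len(stats_in_order)
    K = sum(member_flags)
    nr = sum(abs(s) ** weight for s, m in zip(stats_in_order, member_flags) if m)
    running, cur = [], 0.0
    for s, m in zip(stats_in_order, member_flags):
        if m:
            cur += (abs(s) ** weight / nr) if nr > 0 else 1.0 / K
        else:
            cur -= 1.0 / (N - K)
        running.append(cur)
    hi, lo = max(running), min(running)
    # equal-magnitude extrema resolve to the positive one
    return hi if hi >= -lo else lo


class TestRankStatistic:
    @pytest.mark.parametrize(
        "lfc, p, expected",
        [(2.0, 0.01, 2.0), (-1.0, 0.001, -3.0), (5.0, 1.0, 0.0), (0.0, 0.01, 0.0)],
    )
    def test_signed_log10(self, lfc, p, expected):
        assert rank_statistic(lfc, p) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            rank_statistic(1.0, p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        lfc=st.floats(-10, 10, allow_nan=False),
        p=st.floats(1e-12, 1.0, exclude_min=False),
    )
    def test_antisymmetric_in_fold_change_sign(self, lfc, p):
        assert rank_statistic(-lfc, p) == pytest.approx(-rank_statistic(lfc, p))


class TestRankedList:
    def test_descending_order(self):
        table = pd.DataFrame(
            {
                "gene": ["up", "mid", "down"],
                "log2fc": [1.0, 0.0, -1.0],
                "pvalue": [0.001, 0.5, 0.001],
            }
        )
        ranked = build_ranked_list(table)
        assert ranked.genes == ("up", "mid", "down")
        np.testing.assert_allclose(ranked.stats, [3.0, 0.0, -3.0])

    def test_ties_broken_lexicographically(self):
        table = pd.DataFrame(
            {
                "gene": ["zeta", "alpha"],
                "log2fc": [1.0, 1.0],
                "pvalue": [0.01, 0.01],
            }
        )
        assert build_ranked_list(table).genes == ("alpha", "zeta")

    def test_duplicate_genes_rejected(self):
        table = pd.DataFrame(
            {"gene": ["a", "a"], "log2fc": [1, 2], "pvalue": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            build_ranked_list(table)


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01], [0.01]),
            ([0.02, 0.02, 0.02], [0.02, 0.02, 0.02]),
            # hand step-up: sorted .005,.01,.03,.04 -> .02,.02,.04,.04
            ([0.01, 0.04, 0.03, 0.005], [0.02, 0.04, 0.04, 0.02]),
        ],
    )
    def test_step_up_oracle_values(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_never_below_raw_and_permutation_invariant(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), adj[perm])


class TestDegFilter:
    def test_strict_thresholds(self):
        table = pd.DataFrame(
            {
                "gene": ["in", "edge"],
                "log2fc": [1.5, 1.0],
                "pvalue": [0.01, 0.01],
                "adj_p": [0.04, 0.04],
            }
        )
        assert deg_filter(table) == ["in"]  # log2fc == 1 excluded

    def test_toy_table_three_survivors(self, toy_de_table):
        assert deg_filter(toy_de_table) == ["g1", "g2", "g6"]

    def test_directional_variants(self, toy_de_table):
        assert deg_filter(toy_de_table, direction="up") == ["g1", "g6"]
        assert deg_filter(toy_de_table, direction="down") == ["g2"]

    def test_missing_adjustment_rejected(self, toy_de_table):
        with pytest.raises(ValueError, match="bh_adjust"):
            deg_filter(toy_de_table.drop(columns="adj_p"))


class TestGseaEs:
    def test_top_ranked_single_member_scores_one(self):
        ranked = RankedList(genes=("a", "b", "c"), stats=np.array([3.0, 2.0, 1.0]))
        score = gsea_es(ranked, GeneSet("S", frozenset({"a"})))
        assert score.es == pytest.approx(1.0)
        assert score.leading_edge == ("a",)

    def test_set_covering_universe_rejected(self):
        ranked = RankedList(genes=("a", "b"), stats=np.array([1.0, -1.0]))
        with pytest.raises(ValueError, match="entire ranked list"):
            gsea_es(ranked, GeneSet("S", frozenset({"a", "b"})))

    def test_empty_overlap_is_explicit(self):
        ranked = RankedList(genes=("a", "b"), stats=np.array([1.0, -1.0]))
        score = gsea_es(ranked, GeneSet("S", frozenset({"zzz"})))
        assert score.empty_overlap and np.isnan(score.es)

    def test_matches_brute_force_on_ten_gene_list(self):
        stats_ = np.arange(10, 0, -1, dtype=float)
        ranked = RankedList(genes=tuple("abcdefghij"), stats=stats_)
        members = {"a", "b", "c"}
        score = gsea_es(ranked, GeneSet("S", frozenset(members)))
        flags = [g in members for g in ranked.genes]
        assert score.es == pytest.approx(brute_force_es(stats_, flags))

    def test_exhaustive_small_instances(self):
        """Implementation equals the explicit-loop oracle on all subsets."""
        rng = np.random.default_rng(12)
        for n in (3, 5, 8):
            stats_ = np.sort(rng.normal(size=n))[::-1].copy()
            genes = tuple(f"g{i}" for i in range(n))
            ranked = RankedList(genes=genes, stats=stats_)
            for k in range(1, min(4, n - 1) + 1):
                for combo in itertools.combinations(range(n), k):
                    members = frozenset(genes[i] for i in combo)
                    flags = [i in combo for i in range(n)]
                    es = gsea_es(ranked, GeneSet("S", members)).es
                    assert es == pytest.approx(brute_force_es(stats_, flags))

    def test_leading_edge_for_negative_es(self):
        stats_ = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        ranked = RankedList(genes=tuple("abcdef"), stats=stats_)
        score = gsea_es(ranked, GeneSet("S", frozenset({"e", "f"})))
        assert score.es < 0
        assert set(score.leading_edge) <= {"e", "f"}


@pytest.fixture(scope="module")
def null_ranked():
    rng = np.random.default_rng(99)
    stats_ = np.sort(rng.normal(size=200))[::-1].copy()
    return RankedList(genes=tuple(f"g{i:03d}" for i in range(200)), stats=stats_)


class TestGseaPermutation:
    def test_deterministic_under_seed(self, null_ranked):
        s = GeneSet("S", frozenset({"g000", "g005", "g190"}))
        a = gsea_permutation(null_ranked, s, n_perm=100, seed=5)
        b = gsea_permutation(null_ranked, s, n_perm=100, seed=5)
        assert a == b

    def test_planted_top_set_is_significant(self, null_ranked):
        top = GeneSet("TOP", frozenset(null_ranked.genes[:10]))
        res = gsea_permutation(null_ranked, top, n_perm=1000, seed=1)
        assert res.es > 0 and res.p_perm <= 0.01

    def test_null_p_values_not_anticonservative(self, null_ranked):
        """Random sets yield roughly uniform permutation p-values."""
        rng = np.random.default_rng(7)
        hits = 0
        reps = 200
        for r in range(reps):
            members = frozenset(rng.choice(null_ranked.genes, 10, replace=False))
            res = gsea_permutation(
                null_ranked, GeneSet("R", members), n_perm=200, seed=1000 + r
            )
            hits += res.p_perm <= 0.05
        assert 0.01 <= hits / reps <= 0.12

    def test_too_few_permutations_rejected(self, null_ranked):
        s = GeneSet("S", frozenset({"g000"}))
        with pytest.raises(ValueError, match="at least 10"):
            gsea_permutation(null_ranked, s, n_perm=5)


class TestOra:
    def test_perfect_containment_small_universe(self):
        """N=10, K=n=k=3: p = 1/C(10,3) = 1/120."""
        universe = [f"u{i}" for i in range(10)]
        s = GeneSet("S", frozenset(universe[:3]))
        res = ora_hypergeom(universe[:3], s, universe)
        assert res.p_hyper == pytest.approx(1 / 120)
        assert (res.k, res.n, res.K, res.N) == (3, 3, 3, 10)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"u{i}" for i in range(10)]
        s = GeneSet("S", frozenset(universe[:3]))
        res = ora_hypergeom(universe[5:8], s, universe)
        assert res.k == 0 and res.p_hyper == pytest.approx(1.0)

    def test_deg_outside_universe_rejected(self):
        s = GeneSet("S", frozenset({"u1"}))
        with pytest.raises(ValueError, match="not in universe"):
            ora_hypergeom(["stranger"], s, ["u1", "u2"])

    def test_monte_carlo_agreement(self):
        """sf tail matches sampled overlap frequencies within 3 SE."""
        N, K, n, k = 30, 8, 10, 4
        rng = np.random.default_rng(2)
        draws = rng.hypergeometric(K, N - K, n, size=100_000)
        freq = np.mean(draws >= k)
        universe = [f"u{i}" for i in range(N)]
        s = GeneSet("S", frozenset(universe[:K]))
        deg = universe[: k] + universe[K : K + (n - k)]
        res = ora_hypergeom(deg, s, universe)
        se = np.sqrt(res.p_hyper * (1 - res.p_hyper) / 100_000)
        assert abs(freq - res.p_hyper) < 3 * se


class TestActivityScores:
    def test_constant_genes_score_zero(self):
        expr = pd.DataFrame(
            {"a": [5.0, 5.0, 5.0], "b": [1.0, 1.0, 1.0]},
            index=["s1", "s2", "s3"],
        )
        scores = set_activity_scores(expr, GeneSet("S", frozenset({"a", "b"})))
        np.testing.assert_allclose(scores, 0.0)

    def test_two_sample_z_scores(self):
        expr = pd.DataFrame({"a": [1.0, 3.0]}, index=["s1", "s2"])
        scores = set_activity_scores(expr, GeneSet("S", frozenset({"a"})))
        np.testing.assert_allclose(scores, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_empty_intersection_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no genes"):
            set_activity_scores(expr, GeneSet("S", frozenset({"zzz"})))


class TestRankSum:
    def test_identical_groups_give_p_one(self):
        res = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.exact and res.pvalue == pytest.approx(1.0)

    def test_fully_separated_pairs(self):
        """a={1,2} vs b={3,4}: 2 of C(4,2)=6 assignments as extreme."""
        res = ranksum_test([1.0, 2.0], [3.0, 4.0])
        assert res.exact and res.pvalue == pytest.approx(1 / 3)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=6), rng.normal(size=7)
        ours = ranksum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_asymptotic_close_to_exact_at_eight_per_group(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=8), rng.normal(0.5, 1.0, size=8)
        exact = ranksum_test(a, b)
        approx = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert exact.exact
        assert abs(exact.pvalue - approx.pvalue) < 0.02

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ranksum_test([1.0], [2.0, 3.0])
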