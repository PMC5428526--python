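import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclenbias.stats import (
    GeneSetCategory,
    benjamini_hochberg,
    category_length_spread_test,
    enrich,
    hypergeometric_test,
    read_gmt,
    wilcoxon_rank_sum,
    write_gmt,
)


def brute_force_rank_sum_p(x, y, alternative="two_sided"):
    """Enumerate all C(n+m, n) rank assignments (tie-free samples only)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in x)
    sums = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
    total = len(sums)
    p_less = sum(s <= w_obs for s in sums) / total
    p_greater = sum(s >= w_obs for s in sums) / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


class TestWilcoxonRankSum:
    def test_small_two_sided_exact(self):
        w, p = wilcoxon_rank_sum([1, 2], [3, 4], "two_sided")
        assert w == 3  # ranks 1 + 2
        assert p == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two_sided")
        assert p == pytest.approx(1.0, abs=0.01)

    def test_disjoint_samples_one_sided(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5], [10, 11, 12, 13, 14], "less")
        assert p == pytest.approx(1 / math.comb(10, 5))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n,m,seed", [(2, 3, 0), (4, 4, 1), (5, 5, 2),
                                          (3, 7, 3), (6, 4, 4)])
    @pytest.mark.parametrize("alternative", ["two_sided", "less", "greater"])
    def test_exact_path_matches_enumeration(self, n, m, seed, alternative):
        rng = np.random.default_rng(seed)
        values = rng.permutation(np.arange(n + m, dtype=float) * 1.7 + 0.3)
        x, y = values[:n].tolist(), values[n:].tolist()
        _, p = wilcoxon_rank_sum(x, y, alternative)
        assert p == pytest.approx(brute_force_rank_sum_p(x, y, alternative),
                                  abs=1e-12)

    def test_asymptotic_reasonable_on_large_shifted_samples(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(x, y, "less")
        assert p < 1e-10


def brute_force_hypergeom_upper(k, K, n, N):
    """Oracle: sum the exact PMF over the upper tail with math.comb."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometric:
    def test_closed_form_case(self):
        assert hypergeometric_test(4, 4, 5, 10) == pytest.approx(6 / 252)

    def test_degenerate_tails(self):
        assert hypergeometric_test(0, 3, 4, 10) == pytest.approx(1.0)
        assert hypergeometric_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_arguments(self):
        with pytest.raises(ValueError):
            hypergeometric_test(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_test(1, 11, 5, 10)

    def test_matches_enumeration_for_all_small_configurations(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = brute_force_hypergeom_upper(k, K, n, N)
                        assert hypergeometric_test(k, K, n, N) == pytest.approx(
                            expected, abs=1e-12
                        )


def textbook_bh(p):
    """Step-up BH: sort, scale by m/i, enforce monotonicity from the top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestBenjaminiHochberg:
    def test_matches_textbook_step_up(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(benjamini_hochberg(p), textbook_bh(p),
                                       atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2,
                    max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, p):
        adj = benjamini_hochberg(p)
        assert ((adj > 0) & (adj <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(p) - 1e-12).all()


class TestEnrich:
    def make_universe(self, n):
        return {f"g{i}" for i in range(n)}

    def test_category_equal_to_set_is_significant(self):
        universe = self.make_universe(20)
        gene_set = {f"g{i}" for i in range(10)}
        cats = [GeneSetCategory("c1", "match", frozenset(gene_set))]
        table = enrich(gene_set, cats, universe)
        assert table["p_value"].iloc[0] == pytest.approx(
            1 / math.comb(20, 10), rel=1e-9
        )
        assert bool(table["significant"].iloc[0])

    def test_disjoint_category_not_significant(self):
        universe = self.make_universe(20)
        cats = [GeneSetCategory("c1", "none", frozenset({"g15", "g16"}))]
        table = enrich({f"g{i}" for i in range(5)}, cats, universe)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)
        assert not bool(table["significant"].iloc[0])

    def test_duplicate_categories_share_statistics(self):
        universe = self.make_universe(30)
        members = frozenset({"g1", "g2", "g3"})
        cats = [GeneSetCategory("c1", "a", members),
                GeneSetCategory("c2", "b", members)]
        table = enrich({"g1", "g2", "g5", "g6"}, cats, universe)
        assert table["p_value"].iloc[0] == table["p_value"].iloc[1]
        assert table["fdr"].iloc[0] == table["fdr"].iloc[1]

    def test_median_member_length_over_universe_members(self):
        universe = self.make_universe(10)
        cats = [GeneSetCategory("c1", "x", frozenset({"g0", "g1", "g999"}))]
        lengths = {"g0": 100.0, "g1": 300.0, "g999": 10_000.0}
        table = enrich({"g0"}, cats, universe, lengths=lengths)
        # g999 is outside the universe, so the median spans g0 and g1 only
        assert table["median_member_length"].iloc[0] == 200.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            enrich(set(), [], set())

    def test_null_calibration(self, rng):
        # uniformly drawn gene sets should rarely enrich anything
        universe = sorted(self.make_universe(200))
        cats = [
            GeneSetCategory(f"c{j}", "x",
                            frozenset(rng.choice(universe, 20, replace=False)))
            for j in range(30)
        ]
        n_sig = 0
        reps = 40
        for _ in range(reps):
            gene_set = set(rng.choice(universe, 50, replace=False))
            table = enrich(gene_set, cats, set(universe))
            n_sig += int(table["significant"].sum())
        assert n_sig / (reps * 30) <= 0.05


class TestCategoryLengthSpread:
    def test_ratio_arithmetic(self):
        a = [0.0, 2.0, 4.0]  # var 4
        b = [0.0, 1.0, 2.0]  # var 1
        F, _ = category_length_spread_test(a, b)
        assert F == pytest.approx(4.0)

    def test_swap_inverts_f_preserves_p(self, rng):
        a = rng.lognormal(8, 1.0, 30)
        b = rng.lognormal(8, 0.5, 30)
        F_ab, p_ab = category_length_spread_test(a, b)
        F_ba, p_ba = category_length_spread_test(b, a)
        assert F_ab == pytest.approx(1 / F_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_log_scale_option(self, rng):
        a = rng.lognormal(8, 1.0, 40)
        F_raw, _ = category_length_spread_test(a, a * 10)
        F_log, _ = category_length_spread_test(a, a * 10, log_scale=True)
        # multiplying lengths by 10 changes raw variance but not log spread
        assert F_raw == pytest.approx(1 / 100)
        assert F_log == pytest.approx(1.0)

    def test_zero_variance_denominator_errors(self):
        with pytest.raises(ValueError):
            category_length_spread_test([1.0, 2.0], [3.0, 3.0])


class TestGmt:
    def test_round_trip(self, tmp_path):
        cats = [
            GeneSetCategory("GO:1", "alpha", frozenset({"a", "b"})),
            GeneSetCategory("GO:2", "beta", frozenset({"c"})),
        ]
        path = tmp_path / "sets.gmt"
        write_gmt(cats, path)
        back = read_gmt(path)
        assert back == cats

    def test_malformed_line_errors(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_id\tname_but_no_members\n")
        with pytest.raises(ValueError, match="members"):
            read_gmt(path)
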