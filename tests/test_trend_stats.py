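"""Trend tests, rank correlation, U test and normality check."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mulchdeg import trend_stats as ts


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_perfect_monotone(self):
        r = ts.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert r.rho == pytest.approx(1.0)

    def test_equals_pearson_on_ranks(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12) + 0.5 * x
        y[3] = y[5]  # introduce a tie
        r = ts.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert r.rho == pytest.approx(sps.pearsonr(rx, ry).statistic, rel=1e-12)
        assert r.rho == pytest.approx(sps.spearmanr(x, y).statistic, rel=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert ts.spearman(x, -y).rho == pytest.approx(-ts.spearman(x, y).rho)

    def test_pair_order_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        perm = rng.permutation(8)
        assert ts.spearman(x[perm], y[perm]).rho == pytest.approx(
            ts.spearman(x, y).rho
        )

    def test_constant_vector_undefined(self):
        r = ts.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(r.rho) and r.p_method == "undefined"

    def test_exact_permutation_p_matches_brute_force(self, rng):
        """Permutation p at n=5 equals direct enumeration of all 120
        orderings via an independent statistic (sum of rank products)."""
        x, y = rng.normal(size=5), rng.normal(size=5)
        r = ts.spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        obs = abs(sps.pearsonr(rx, ry).statistic)
        hits = sum(
            abs(sps.pearsonr(np.array(p), ry).statistic) >= obs - 1e-12
            for p in itertools.permutations(rx)
        )
        assert r.p_value == pytest.approx(hits / math.factorial(5))
        assert r.p_method == "exact-permutation"

    def test_t_approximation_close_to_exact_at_small_n(self, rng):
        diffs = []
        for _ in range(30):
            x, y = rng.normal(size=5), rng.normal(size=5)
            pe = ts.spearman(x, y).p_value
            pt = ts.spearman(x, y, exact_max_n=0).p_value
            diffs.append(abs(pe - pt))
        assert max(diffs) < 0.10

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            ts.spearman([1, 2, 3], [1, 2, 3])


# ---------------------------------------------------------------------------
# PAVA


def brute_force_isotonic(means, weights):
    """Minimum-SSE monotone fit by exhaustive search over contiguous block
    partitions (oracle; the optimum is blockwise weighted means)."""
    m, w = np.asarray(means, float), np.asarray(weights, float)
    n = m.size
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        edges = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        fit = np.empty(n)
        for a, b in zip(edges, edges[1:]):
            fit[a:b] = np.average(m[a:b], weights=w[a:b])
        if np.all(np.diff(fit) >= -1e-12):
            sse = float(np.sum(w * (fit - m) ** 2))
            if sse < best_sse - 1e-12:
                best, best_sse = fit, sse
    return best


class TestPava:
    def test_monotone_input_unchanged(self):
        np.testing.assert_allclose(ts.pava_isotonic([1, 2, 3]), [1, 2, 3])

    def test_single_pooled_block(self):
        np.testing.assert_allclose(ts.pava_isotonic([3, 1]), [2, 2])

    def test_matches_brute_force_partition_oracle(self, rng):
        for _ in range(60):
            m = rng.normal(size=6)
            w = rng.uniform(0.5, 3.0, size=6)
            np.testing.assert_allclose(
                ts.pava_isotonic(m, w), brute_force_isotonic(m, w), atol=1e-10
            )

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10))
    @settings(max_examples=150, derandomize=True)
    def test_output_monotone_and_mean_preserving(self, means):
        w = np.ones(len(means))
        out = ts.pava_isotonic(means, w)
        assert np.all(np.diff(out) >= -1e-9)
        assert np.average(out, weights=w) == pytest.approx(
            np.average(means, weights=w), abs=1e-9
        )

    def test_decrease_direction(self):
        out = ts.pava_isotonic([1, 3], direction="decrease")
        np.testing.assert_allclose(out, [2, 2])


# ---------------------------------------------------------------------------
# Williams / Shirley-Williams


def _null_groups(rng, k=4, n=6):
    return ts.OrderedGroups(rng.normal(size=n),
                            [(f"g{i}", rng.normal(size=n)) for i in range(1, k + 1)])


class TestWilliams:
    def test_identical_constants_no_rejection(self):
        g = ts.OrderedGroups(np.full(4, 2.0), [("a", np.full(4, 2.0)),
                                               ("b", np.full(4, 2.0))])
        res = ts.williams_test(g, n_null_reps=2000)
        assert res.rejected_labels == []

    def test_large_effect_rejected(self, rng):
        g = ts.OrderedGroups(
            rng.normal(0, 1, 10),
            [(f"g{i}", rng.normal(0, 1, 10) + (5.0 if i == 4 else 0.0))
             for i in range(1, 5)],
        )
        res = ts.williams_test(g, n_null_reps=10_000)
        assert res.stages[0].reject  # top dose

    def test_single_stage_reference_is_student_t(self):
        """With one treatment group the statistic is an ordinary pooled-t
        comparison, so the Monte-Carlo reference value must match the
        exact Student-t quantile (within MC error)."""
        cv = ts.null_critical_values("williams", (8, 8), 0.025, 200_000, seed=7)
        assert cv[0] == pytest.approx(sps.t.ppf(0.975, 14), abs=0.03)

    def test_reference_values_reproducible_across_seeds(self):
        a = ts.null_critical_values("williams", (6, 6, 6), 0.025, 100_000, seed=1)
        b = ts.null_critical_values("williams", (6, 6, 6), 0.025, 100_000, seed=2)
        np.testing.assert_allclose(a, b, atol=0.05)

    def test_stepdown_rejections_contiguous(self, rng):
        for i in range(30):
            shift = rng.uniform(0, 3)
            g = ts.OrderedGroups(
                rng.normal(size=6),
                [(f"g{j}", rng.normal(size=6) + shift * j / 4) for j in range(1, 5)],
            )
            res = ts.williams_test(g, n_null_reps=5000)
            rejected = [s.reject for s in res.stages]
            # contiguous prefix of the top-down stage order
            assert rejected == sorted(rejected, reverse=True)

    def test_degenerate_zero_variance(self):
        g = ts.OrderedGroups(np.full(3, 1.0), [("a", np.full(3, 1.0)),
                                               ("b", np.full(3, 2.0))])
        res = ts.williams_test(g, n_null_reps=2000)
        assert res.stages[0].reject and not res.stages[1].reject

    def test_too_small_groups_error(self):
        with pytest.raises(ValueError):
            ts.williams_test(ts.OrderedGroups([1.0, 2.0], [("a", [1.0])]))


class TestShirleyWilliams:
    def test_identical_constants_no_rejection(self):
        g = ts.OrderedGroups(np.full(4, 5.0), [("a", np.full(4, 5.0)),
                                               ("b", np.full(4, 5.0))])
        res = ts.shirley_williams_test(g, n_null_reps=2000)
        assert res.rejected_labels == []

    def test_monotone_shift_rejected(self, rng):
        g = ts.OrderedGroups(
            rng.normal(size=8),
            [(f"g{i}", rng.normal(size=8) + 3.0 * i / 4) for i in range(1, 5)],
        )
        res = ts.shirley_williams_test(g, n_null_reps=10_000)
        assert res.stages[0].reject

    def test_invariant_under_monotone_transformation(self, rng):
        g = ts.OrderedGroups(
            rng.lognormal(size=6),
            [(f"g{i}", rng.lognormal(size=6) * (1 + i)) for i in range(1, 4)],
        )
        res1 = ts.shirley_williams_test(g, n_null_reps=5000)
        g2 = ts.OrderedGroups(np.log(g.control),
                              [(lbl, np.log(v)) for lbl, v in g.groups])
        res2 = ts.shirley_williams_test(g2, n_null_reps=5000)
        assert [s.reject for s in res1.stages] == [s.reject for s in res2.stages]
        for s1, s2 in zip(res1.stages, res2.stages):
            assert s1.statistic == pytest.approx(s2.statistic, rel=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def brute_force_mwu_p(a, b):
    """Two-sided exact p by enumerating labelings, with U counted directly
    as pairwise wins (+ half-ties) — independent of the rank-sum path."""
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_of(idx):
        sa = pooled[list(idx)]
        sb = np.delete(pooled, list(idx))
        wins = sum((x > y) + 0.5 * (x == y) for x in sa for y in sb)
        return wins

    mu = n1 * (len(pooled) - n1) / 2.0
    u_obs = u_of(range(n1))
    dev = abs(u_obs - mu)
    labelings = list(itertools.combinations(range(len(pooled)), n1))
    hits = sum(abs(u_of(idx) - mu) >= dev - 1e-12 for idx in labelings)
    return u_obs, hits / len(labelings)


class TestMannWhitney:
    def test_separated_pairs(self):
        r = ts.mann_whitney_u([1, 2], [3, 4])
        assert r.u_statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)
        assert r.method == "exact"

    def test_identical_multisets(self):
        r = ts.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_exact_matches_scipy_without_ties(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=6)
        r = ts.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self, rng):
        vals = rng.integers(0, 4, size=9).astype(float)  # many ties
        a, b = vals[:4], vals[4:]
        r = ts.mann_whitney_u(a, b)
        u_ref, p_ref = brute_force_mwu_p(a, b)
        assert r.u_statistic == pytest.approx(u_ref)
        assert r.p_value == pytest.approx(p_ref)

    def test_swap_and_shift_invariance(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=5)
        p1 = ts.mann_whitney_u(a, b).p_value
        assert ts.mann_whitney_u(b, a).p_value == pytest.approx(p1)
        assert ts.mann_whitney_u(a + 7.7, b + 7.7).p_value == pytest.approx(p1)

    def test_exact_vs_normal_approximation(self, rng):
        diffs = []
        for _ in range(25):
            a, b = rng.normal(size=6), rng.normal(size=6)
            pe = ts.mann_whitney_u(a, b).p_value
            pn = ts.mann_whitney_u(a, b, exact_max_n=0).p_value
            diffs.append(abs(pe - pn))
        assert max(diffs) < 0.03

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ts.mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# KS normality


class TestKsNormality:
    def test_normal_sample_not_rejected(self):
        x = np.random.default_rng(0).normal(3.0, 2.0, size=500)
        _, p = ts.ks_normality(x)
        assert p > 0.05

    def test_exponential_sample_rejected(self, rng):
        x = rng.exponential(size=500)
        _, p = ts.ks_normality(x)
        assert p < 0.01

    def test_statistic_equals_ecdf_scan(self, rng):
        x = rng.normal(size=40)
        stat, _ = ts.ks_normality(x)
        xs = np.sort(x)
        cdf = sps.norm.cdf(xs, x.mean(), x.std(ddof=1))
        n = x.size
        d = max(
            max(np.arange(1, n + 1) / n - cdf),
            max(cdf - np.arange(0, n) / n),
        )
        assert stat == pytest.approx(d, abs=1e-12)

    def test_plain_variant_less_sensitive(self, rng):
        # the plain-KS p (moments estimated but uncorrected) is larger
        x = rng.normal(size=100)
        _, p_lill = ts.ks_normality(x)
        _, p_plain = ts.ks_normality(x, lilliefors=False)
        assert p_plain >= p_lill - 1e-9

    def test_constant_data_degenerate(self):
        stat, p = ts.ks_normality([2.0] * 10)
        assert p == 0.0

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            ts.ks_normality([1.0, 2.0])
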