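"""Unit, oracle and property tests for the statistics suite.

The Mann-Whitney oracle enumerates group labelings and counts pairwise wins
directly (no ranks); the Friedman oracle recomputes ranks by sorting.  Both
stay independent of the implementation paths they check.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from brillmap.stats import (
    GroupSamples,
    RepeatedMeasuresTable,
    analysis_policy,
    chen_shapiro,
    chisq_upper_tail,
    dunn_friedman_posthoc,
    dunn_kw_posthoc,
    effect_size_r,
    friedman,
    kendalls_w,
    kruskal_wallis,
    kw_eta_squared,
    mann_whitney_exact,
    midrank,
    students_t_two_sample,
)

# ---------------------------------------------------------------------------
# independent oracles


def oracle_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of labelings.

    U_x counts pairwise wins of x over y (ties count 0.5); the permutation
    distribution comes from relabeling the pooled observations.
    """

    def u_stat(a, b):
        return sum(
            (1.0 if ai > bj else 0.5 if ai == bj else 0.0) for ai in a for bj in b
        )

    pooled = list(x) + list(y)
    n_x = len(x)
    u_obs = u_stat(x, y)
    dist = []
    for idx in itertools.combinations(range(len(pooled)), n_x):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        dist.append(u_stat(a, b))
    dist = np.array(dist)
    lower = np.mean(dist <= u_obs)
    upper = np.mean(dist >= u_obs)
    return min(1.0, 2.0 * min(lower, upper))


def oracle_friedman_chi2(table):
    """Friedman statistic from scratch: sort-based midranks, plain formula."""
    n, k = table.shape
    rank_sums = [0.0] * k
    for row in table:
        order = sorted(range(k), key=lambda j: row[j])
        ranks = [0.0] * k
        i = 0
        while i < k:
            j = i
            while j + 1 < k and row[order[j + 1]] == row[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for m in range(i, j + 1):
                ranks[order[m]] = avg
            i = j + 1
        for j in range(k):
            rank_sums[j] += ranks[j]
    s = sum(r * r for r in rank_sums)
    return 12.0 / (n * k * (k + 1)) * s - 3.0 * n * (k + 1)


# ---------------------------------------------------------------------------
# midrank


class TestMidrank:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((3, 1, 2), (3, 1, 2)),
            ((5, 5, 1), (2.5, 2.5, 1)),
            ((1, 1, 1), (2, 2, 2)),
        ],
    )
    def test_examples(self, values, expected):
        assert midrank(values) == pytest.approx(expected)

    @given(st.lists(st.integers(-5, 5), min_size=6, max_size=6))
    def test_rank_sum_invariant(self, values):
        assert midrank(values).sum() == pytest.approx(21.0)


# ---------------------------------------------------------------------------
# Friedman + Kendall's W + Dunn


def concordant_5x3():
    rng = np.random.default_rng(5)
    base = np.sort(rng.random((5, 3)), axis=1)[:, ::-1]  # strictly decreasing
    return RepeatedMeasuresTable(base, conditions=("0 min", "30 min", "45 min"))


def ranksum_12_5_7_4x3():
    # A ranked 3 by all; B ranked 1 by three subjects, 2 by one; C the rest
    values = np.array(
        [[3.0, 1.0, 2.0], [3.0, 1.0, 2.0], [3.0, 1.0, 2.0], [3.0, 2.0, 1.0]]
    )
    return RepeatedMeasuresTable(values, conditions=("0 dpa", "15 dpa", "30 dpa"))


class TestFriedman:
    def test_complete_concordance_statistic(self):
        assert friedman(concordant_5x3()).statistic_value == pytest.approx(10.0)

    def test_complete_concordance_p(self):
        assert friedman(concordant_5x3()).p_value == pytest.approx(0.00674, abs=5e-6)

    def test_complete_concordance_w(self):
        assert friedman(concordant_5x3()).effect_size[1] == pytest.approx(1.0)

    def test_ranksum_12_5_7_statistic(self):
        assert friedman(ranksum_12_5_7_4x3()).statistic_value == pytest.approx(6.5)

    def test_ranksum_12_5_7_p(self):
        assert friedman(ranksum_12_5_7_4x3()).p_value == pytest.approx(
            0.03877, abs=5e-6
        )

    def test_ranksum_12_5_7_w(self):
        w = friedman(ranksum_12_5_7_4x3()).effect_size[1]
        assert w == pytest.approx(0.8125)
        assert round(w, 2) == 0.81

    def test_full_ties_zero(self):
        table = RepeatedMeasuresTable(np.ones((4, 3)))
        assert friedman(table).statistic_value == 0.0
        assert friedman(table).p_value == 1.0

    def test_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(2, 7)
            k = rng.integers(2, 5)
            table = rng.integers(0, 5, size=(n, k)).astype(float)  # with ties
            got = friedman(RepeatedMeasuresTable(table)).statistic_value
            assert got == pytest.approx(
                max(oracle_friedman_chi2(table), 0.0), abs=1e-10
            )

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError):
            RepeatedMeasuresTable(np.array([[1.0, np.nan], [2.0, 3.0]]))

    @given(
        st.lists(
            st.lists(st.integers(-10, 10), min_size=3, max_size=3),
            min_size=3,
            max_size=6,
        )
    )
    def test_monotone_transform_invariance(self, rows):
        table = np.array(rows, dtype=float)
        got = friedman(RepeatedMeasuresTable(table)).statistic_value
        transformed = np.exp(table / 10.0)  # strictly monotone
        got2 = friedman(RepeatedMeasuresTable(transformed)).statistic_value
        assert got == pytest.approx(got2, abs=1e-9)

    def test_concordance_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n, k = int(rng.integers(2, 6)), int(rng.integers(2, 5))
            table = rng.standard_normal((n, k))
            res = friedman(RepeatedMeasuresTable(table))
            assert res.statistic_value <= n * (k - 1) + 1e-9
            assert 0.0 <= res.effect_size[1] <= 1.0 + 1e-12

    def test_type_one_error_band(self):
        # chi-square approximation at N_A=5, k=3 is mildly conservative
        rng = np.random.default_rng(42)
        rejections = sum(
            friedman(RepeatedMeasuresTable(rng.standard_normal((5, 3)))).p_value
            < 0.05
            for _ in range(10_000)
        )
        assert 0.02 <= rejections / 10_000 <= 0.06


class TestKendallsW:
    @pytest.mark.parametrize(
        "chi2,n,k,expected",
        [(10.0, 5, 3, 1.0), (6.5, 4, 3, 0.8125), (0.0, 7, 4, 0.0)],
    )
    def test_examples(self, chi2, n, k, expected):
        assert kendalls_w(chi2, n, k) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            kendalls_w(1.0, 1, 3)


class TestDunnFriedman:
    def test_concordant_extreme_pair(self):
        ph = dunn_friedman_posthoc(concordant_5x3())
        extreme = [p for p in ph if p.pair == ("0 min", "45 min")][0]
        assert extreme.p_adjusted == pytest.approx(0.0047, abs=5e-5)

    def test_ranksum_12_5_7_extreme_pair(self):
        ph = dunn_friedman_posthoc(ranksum_12_5_7_4x3())
        extreme = [p for p in ph if p.pair == ("0 dpa", "15 dpa")][0]
        assert extreme.p_adjusted == pytest.approx(0.03998, abs=2e-5)

    def test_identical_conditions_all_one(self):
        table = RepeatedMeasuresTable(np.ones((5, 3)))
        assert all(p.p_adjusted == 1.0 for p in dunn_friedman_posthoc(table))

    def test_adjusted_geq_raw(self):
        rng = np.random.default_rng(3)
        table = RepeatedMeasuresTable(rng.standard_normal((5, 4)))
        for pr in dunn_friedman_posthoc(table):
            raw = 2.0 * sps.norm.sf(pr.z)
            assert pr.p_adjusted >= raw - 1e-15
            assert 0.0 <= pr.p_adjusted <= 1.0


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_two_groups_total_separation(self):
        groups = GroupSamples((np.array([1.0, 2.0]), np.array([3.0, 4.0])))
        # hand ranks: 1,2 | 3,4 -> H = 12/(4*5) * (9/2 + 49/2) - 3*5 = 2.4
        assert kruskal_wallis(groups).statistic_value == pytest.approx(2.4)

    def test_all_equal_is_degenerate(self):
        groups = GroupSamples((np.ones(3), np.ones(3)))
        with pytest.raises(ValueError):
            kruskal_wallis(groups)

    def test_printed_p_at_df4(self):
        assert chisq_upper_tail(15.21273, 4) == pytest.approx(0.00428, abs=5e-6)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            sizes = rng.integers(2, 6, size=rng.integers(2, 5))
            groups = tuple(
                rng.integers(0, 6, size=s).astype(float) for s in sizes
            )
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            got = kruskal_wallis(GroupSamples(groups))
            ref = sps.kruskal(*groups)
            assert got.statistic_value == pytest.approx(ref.statistic, abs=1e-10)
            assert got.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestKwEtaSquared:
    def test_inferred_n23(self):
        eta2 = kw_eta_squared(15.21273, 5, 23)
        assert eta2 == pytest.approx(0.623, abs=5e-4)
        assert round(eta2, 2) == 0.62

    def test_zero_at_h_equals_k_minus_one(self):
        assert kw_eta_squared(4.0, 5, 23) == 0.0

    def test_monotone_in_h(self):
        assert kw_eta_squared(10.0, 5, 23) < kw_eta_squared(12.0, 5, 23)


class TestDunnKw:
    def test_identical_groups(self):
        rng = np.random.default_rng(2)
        g = rng.standard_normal(5)
        ph = dunn_kw_posthoc(GroupSamples((g.copy(), g.copy())))
        assert all(p.p_adjusted == 1.0 for p in ph)

    def test_two_separated_groups_of_four_formula(self):
        groups = GroupSamples(
            (np.array([1.0, 2.0, 3.0, 4.0]), np.array([5.0, 6.0, 7.0, 8.0]))
        )
        (pr,) = dunn_kw_posthoc(groups)
        # brute force: mean ranks 2.5 vs 6.5; sigma = sqrt(8*9/12 * (1/4+1/4))
        z_expected = 4.0 / math.sqrt(6.0 * 0.5)
        assert pr.z == pytest.approx(z_expected, abs=1e-12)

    def test_monotone_shift_increases_extreme_z(self):
        rng = np.random.default_rng(8)
        a, b, c = (rng.standard_normal(4) for _ in range(3))
        z1 = dunn_kw_posthoc(GroupSamples((a, b, c + 1.0)))[1].z
        z2 = dunn_kw_posthoc(GroupSamples((a, b, c + 10.0)))[1].z
        assert z2 >= z1


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_complete_separation_p(self):
        res = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.statistic_value == 0.0
        assert res.p_value == pytest.approx(2.0 / 70.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.02857, abs=5e-6)

    def test_complete_separation_z(self):
        res = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.posthoc[0].z == pytest.approx(-2.16506, abs=5e-6)
        assert res.posthoc[0].z == pytest.approx((0 - 8 + 0.5) / math.sqrt(12))

    def test_effect_size_r(self):
        res = mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.effect_size[1] == pytest.approx(0.7655, abs=5e-5)
        assert effect_size_r(-2.16506, 8) == pytest.approx(0.7655, abs=5e-5)

    def test_identical_samples(self):
        res = mann_whitney_exact([1.0, 2.0], [1.0, 2.0])
        assert res.statistic_value == pytest.approx(2.0)  # n^2/2
        assert res.p_value == 1.0
        assert res.posthoc[0].z == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_oracle_all_small_sizes(self):
        rng = np.random.default_rng(31)
        for n_x in range(1, 7):
            for n_y in range(1, 7):
                x = rng.integers(0, 8, size=n_x).astype(float)
                y = rng.integers(0, 8, size=n_y).astype(float)
                got = mann_whitney_exact(x, y).p_value
                assert got == pytest.approx(oracle_mw_p(x, y), abs=1e-12), (
                    n_x,
                    n_y,
                    x,
                    y,
                )

    @given(
        st.lists(st.integers(0, 20), min_size=2, max_size=5),
        st.lists(st.integers(0, 20), min_size=2, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, x, y):
        r1 = mann_whitney_exact(x, y)
        fx = [math.exp(v / 5.0) for v in x]
        fy = [math.exp(v / 5.0) for v in y]
        r2 = mann_whitney_exact(fx, fy)
        assert r1.statistic_value == pytest.approx(r2.statistic_value)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15) + 1.0
        res = mann_whitney_exact(x, y)
        assert res.statistic_name.endswith("normal")
        assert 0.0 <= res.p_value <= 1.0


# ---------------------------------------------------------------------------
# chi-square backend


class TestChisqUpperTail:
    @pytest.mark.parametrize(
        "x,df,expected,tol",
        [
            (10.0, 2, 0.00674, 5e-6),
            (6.5, 2, 0.03877, 5e-6),
            (15.21273, 4, 0.00428, 5e-6),
            (0.0, 3, 1.0, 0.0),
        ],
    )
    def test_printed_values(self, x, df, expected, tol):
        assert chisq_upper_tail(x, df) == pytest.approx(expected, abs=tol)

    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_df2_closed_form(self, x):
        assert chisq_upper_tail(x, 2) == pytest.approx(math.exp(-x / 2.0), abs=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            chisq_upper_tail(-1.0, 2)
        with pytest.raises(ValueError):
            chisq_upper_tail(1.0, 0)


# ---------------------------------------------------------------------------
# t-test, Chen-Shapiro, policy


class TestStudentsT:
    def test_identical_samples_errors_on_zero_variance(self):
        with pytest.raises(ValueError):
            students_t_two_sample([1.0, 1.0], [1.0, 1.0])

    def test_same_distribution_zero_t(self):
        res = students_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic_value == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_formula(self):
        x, y = np.array([0.0, 1.0]), np.array([10.0, 11.0])
        res = students_t_two_sample(x, y)
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2.0
        expected = (x.mean() - y.mean()) / math.sqrt(sp2 * (0.5 + 0.5))
        assert res.statistic_value == pytest.approx(expected)
        assert res.df == 2

    def test_swap_negates_t(self):
        x, y = [0.0, 1.0, 2.0], [5.0, 6.0, 9.0]
        r1 = students_t_two_sample(x, y)
        r2 = students_t_two_sample(y, x)
        assert r1.statistic_value == pytest.approx(-r2.statistic_value)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_scipy(self):
        rng = np.random.default_rng(12)
        x, y = rng.standard_normal(8), rng.standard_normal(6) + 0.5
        res = students_t_two_sample(x, y)
        ref = sps.ttest_ind(x, y)
        assert res.statistic_value == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)


class TestChenShapiro:
    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(25)
        q1, _ = chen_shapiro(x)
        q2, _ = chen_shapiro(3.5 * x + 12.0)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_normal_sample_near_null_median(self):
        rng = np.random.default_rng(1)
        q, reject = chen_shapiro(rng.standard_normal(200))
        assert q == pytest.approx(1.0, abs=0.05)
        assert not reject

    def test_degenerate_two_point_sample_rejected(self):
        rng = np.random.default_rng(1)
        x = np.repeat([0.0, 1.0], 10) + 1e-3 * rng.standard_normal(20)
        _, reject = chen_shapiro(x)
        assert reject

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            chen_shapiro([1.0, 2.0, 3.0])


class TestAnalysisPolicy:
    def test_repeated_measures_goes_friedman(self):
        table = RepeatedMeasuresTable(np.random.default_rng(0).random((5, 3)))
        assert analysis_policy(table) == "friedman"

    def test_two_small_groups_mann_whitney(self):
        g = GroupSamples((np.arange(4.0), np.arange(4.0) + 1))
        assert analysis_policy(g) == "mann_whitney"

    def test_multi_group_kruskal(self):
        g = GroupSamples(tuple(np.random.default_rng(0).random(5) for _ in range(3)))
        assert analysis_policy(g) == "kruskal_wallis"

    def test_large_normal_groups_t_test(self):
        rng = np.random.default_rng(0)
        g = GroupSamples((rng.standard_normal(40), rng.standard_normal(40)))
        assert analysis_policy(g) == "t_test"
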