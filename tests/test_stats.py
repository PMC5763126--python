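"""ANOVA/SNK/Wilcoxon correctness against independent oracles:
scipy.stats.f_oneway, scipy.stats.studentized_range, the sqrt(2)*t
identity, pooled t-tests, and a from-scratch rank-sum enumeration."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from sodkit.stats import (
    one_way_anova,
    pairwise_wilcoxon,
    snk_posthoc,
    studentized_range_cdf,
    studentized_range_quantile,
    survival_proportions,
)


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computation(self):
        res = one_way_anova({"a": [1, 2], "b": [3, 4]})
        assert res.f == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            groups = {
                str(i): rng.normal(rng.normal(), 1.0, size=rng.integers(3, 9))
                for i in range(rng.integers(2, 5))
            }
            res = one_way_anova(groups)
            ref = sps.f_oneway(*groups.values())
            assert res.f == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1, 1], "b": [1, 1]})
        with pytest.raises(ValueError):
            one_way_anova({"a": []})


class TestStudentizedRange:
    @pytest.mark.parametrize("df", [5, 10, 30, 120])
    def test_sqrt2_t_identity_to_4_sig_digits(self, df):
        q = studentized_range_quantile(0.05, 2, df)
        ref = math.sqrt(2) * sps.t.ppf(0.975, df)
        assert q == pytest.approx(ref, rel=5e-5)

    def test_infinite_df_normal_identity(self):
        q = studentized_range_quantile(0.05, 2, math.inf)
        assert q == pytest.approx(math.sqrt(2) * sps.norm.ppf(0.975), rel=1e-6)

    @pytest.mark.parametrize(
        "alpha,k,df", [(0.05, 3, 10), (0.05, 5, 20), (0.01, 3, 15), (0.10, 4, 8)]
    )
    def test_against_scipy_distribution(self, alpha, k, df):
        q = studentized_range_quantile(alpha, k, df)
        ref = sps.studentized_range.ppf(1 - alpha, k, df)
        assert q == pytest.approx(ref, rel=1e-6)

    def test_published_table_value(self):
        assert studentized_range_quantile(0.05, 3, 10) == pytest.approx(3.88, abs=0.005)

    def test_cdf_monotone_and_bounded(self):
        qs = np.linspace(0.1, 8, 25)
        vals = [studentized_range_cdf(q, 3, 12) for q in qs]
        assert all(0 <= v <= 1 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            studentized_range_quantile(0.0, 2, 10)
        with pytest.raises(ValueError):
            studentized_range_quantile(0.05, 1, 10)


class TestSNK:
    def test_identical_groups_nothing_significant(self):
        g = {"a": [1.0, 1.1, 0.9], "b": [1.0, 0.9, 1.1], "c": [1.1, 1.0, 0.9]}
        res = snk_posthoc(g)
        assert not res.significant.to_numpy().any()

    def test_outlying_mean_only(self):
        rng = np.random.default_rng(0)
        g = {
            "a": 0.0 + rng.normal(0, 0.1, 5),
            "b": 0.1 + rng.normal(0, 0.1, 5),
            "c": 10.0 + rng.normal(0, 0.1, 5),
        }
        res = snk_posthoc(g)
        assert res.significant.loc["c", "a"] and res.significant.loc["c", "b"]
        assert not res.significant.loc["a", "b"]

    def test_two_groups_match_pooled_t_test(self, rng):
        agree = 0
        n_sets = 500
        for _ in range(n_sets):
            n1, n2 = rng.integers(3, 10, size=2)
            shift = rng.normal(0, 1.2)
            g = {"a": rng.normal(0, 1, n1), "b": rng.normal(shift, 1, n2)}
            snk_sig = bool(snk_posthoc(g).significant.loc["a", "b"])
            t_sig = sps.ttest_ind(g["a"], g["b"]).pvalue < 0.05
            agree += snk_sig == t_sig
        assert agree == n_sets

    def test_stepwise_closure(self, rng):
        """A non-significant range forces non-significance of all nested
        pairs, whatever the raw range statistics say."""
        for _ in range(50):
            g = {l: rng.normal(rng.normal(0, 0.8), 1, 6) for l in "abcd"}
            res = snk_posthoc(g)
            order, sig = res.order, res.significant
            for i, j in itertools.combinations(range(len(order)), 2):
                if not sig.loc[order[i], order[j]]:
                    for a in range(i, j + 1):
                        for b in range(a + 1, j + 1):
                            assert not sig.loc[order[a], order[b]]

    def test_familywise_error_rate_under_global_null(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 2000
        for _ in range(n_sims):
            g = {l: rng.normal(0, 1, 10) for l in "abc"}
            if snk_posthoc(g, alpha=0.05).significant.to_numpy().any():
                rejections += 1
        assert rejections / n_sims <= 0.07

    def test_decision_matrix_symmetric(self, rng):
        g = {l: rng.normal(i, 1, 5) for i, l in enumerate("abc")}
        m = snk_posthoc(g).significant
        assert (m.to_numpy() == m.to_numpy().T).all()


def _enumeration_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group labelings."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        vals = [sorted(pooled)[i] for i in combo]
        us.append(sum(ranks[v] for v in vals) - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_exact_textbook_case(self):
        p = pairwise_wilcoxon({"a": [1, 2, 3], "b": [4, 5, 6]})["raw"]
        assert p.loc["a", "b"] == pytest.approx(0.100, abs=1e-12)

    def test_identical_groups(self):
        p = pairwise_wilcoxon({"a": [1, 2, 3], "b": [1, 2, 3]})["raw"]
        assert p.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_all_small_sizes(self, rng):
        for n1 in range(2, 7):
            for n2 in range(2, 7):
                x = list(rng.normal(0, 1, n1))
                y = list(rng.normal(0.8, 1, n2))
                got = pairwise_wilcoxon({"a": x, "b": y})["raw"].loc["a", "b"]
                assert got == pytest.approx(_enumeration_rank_sum_p(x, y), abs=1e-10)

    def test_matrix_symmetry_and_holm(self, rng):
        g = {l: list(rng.normal(i, 1, 5)) for i, l in enumerate("abc")}
        mats = pairwise_wilcoxon(g)
        for key in ("raw", "holm"):
            m = mats[key]
            assert (m.to_numpy() == m.to_numpy().T).all()
        assert (mats["holm"].to_numpy() >= mats["raw"].to_numpy() - 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon({"a": [], "b": [1.0]})


class TestSurvival:
    def test_mean_and_se(self):
        res = survival_proportions({"t": [(8, 10), (9, 10), (10, 10)]})
        assert res.loc["t", "proportion_mean"] == pytest.approx(0.9)
        assert res.loc["t", "proportion_se"] == pytest.approx(0.1 / math.sqrt(3))

    def test_single_experiment_flagged(self):
        res = survival_proportions({"t": [(5, 10)]})
        assert res.loc["t", "proportion_mean"] == pytest.approx(0.5)
        assert bool(res.loc["t", "se_undefined"])

    def test_all_dead(self):
        res = survival_proportions({"t": [(0, 10)] * 3})
        assert res.loc["t", "proportion_mean"] == 0.0
        assert res.loc["t", "proportion_se"] == 0.0

    def test_alive_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            survival_proportions({"t": [(11, 10)]})
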