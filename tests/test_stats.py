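"""Group-comparison layer against brute-force and formula oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from interneuron_profiler import stats as st
from interneuron_profiler.errors import InputError, ModelError


def _table(groups: dict) -> pd.DataFrame:
    rows = [{"group": g, "y": v} for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


class TestNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            st.check_normality([1.0, 2.0])

    def test_constant_sample_degenerate(self):
        with pytest.raises(InputError):
            st.check_normality([3.0] * 10)

    def test_exponential_sample_rejected_as_normal(self):
        rng = np.random.default_rng(0)
        res = st.check_normality(rng.exponential(size=100))
        assert res.p < 0.05
        assert not res.normal_at_alpha

    def test_normal_sample_qq_summary(self):
        rng = np.random.default_rng(1)
        res = st.check_normality(rng.normal(size=200))
        assert res.qq_correlation > 0.99
        assert res.p > 0.01


class TestCompareGroupsLm:
    def test_extreme_separation(self):
        rng = np.random.default_rng(2)
        table = _table({"a": rng.normal(0, 1, 20),
                        "b": rng.normal(10, 1, 20)})
        (res,) = st.compare_groups_lm(table, "y")
        assert res.p_adjusted < 0.001
        assert res.significant

    def test_matches_statsmodels_tukeyhsd(self):
        rng = np.random.default_rng(3)
        table = _table({g: rng.normal(m, 1, n)
                        for g, m, n in [("a", 0, 8), ("b", 0.8, 11),
                                        ("c", 1.5, 9)]})
        ours = {r.contrast: r for r in st.compare_groups_lm(table, "y")}
        sm_res = pairwise_tukeyhsd(table["y"], table["group"])
        for (g1, g2), diff, p in zip(
                itertools.combinations(sm_res.groupsunique, 2),
                sm_res.meandiffs, sm_res.pvalues):
            r = ours[(g1, g2)]
            assert np.isclose(r.estimate, -diff, rtol=1e-12)
            assert np.isclose(r.p_adjusted, p, rtol=1e-8, atol=1e-12)

    def test_adjusted_never_below_unadjusted(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            table = _table({g: rng.normal(rng.normal(), 1, 6)
                            for g in "abcd"})
            for r in st.compare_groups_lm(table, "y"):
                assert r.p_adjusted >= r.p_unadjusted
                assert 0 <= r.p_adjusted <= 1

    def test_group_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        table = _table({"a": rng.normal(0, 1, 7), "b": rng.normal(1, 1, 9),
                        "c": rng.normal(2, 1, 8)})
        shuffled = table.sample(frac=1, random_state=0)
        base = {r.contrast: r for r in st.compare_groups_lm(table, "y")}
        for r in st.compare_groups_lm(shuffled, "y"):
            key = r.contrast if r.contrast in base else r.contrast[::-1]
            sign = 1 if r.contrast in base else -1
            assert np.isclose(base[key].estimate, sign * r.estimate)
            assert np.isclose(base[key].p_adjusted, r.p_adjusted)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ModelError):
            st.compare_groups_lm(_table({"a": [1.0, 2.0]}), "y")

    def test_singleton_group_rejected(self):
        with pytest.raises(ModelError):
            st.compare_groups_lm(_table({"a": [1.0, 2.0], "b": [3.0]}), "y")


class TestKruskalDunn:
    def test_all_equal_gives_h_zero(self):
        res = st.kruskal_dunn(_table({"a": [5.0] * 4, "b": [5.0] * 4}), "y")
        assert res.h == 0.0
        assert res.p == 1.0

    def test_h_matches_rank_formula(self):
        groups = {"a": [1.0, 3.0, 5.0], "b": [2.0, 4.0, 6.0],
                  "c": [7.0, 8.0, 9.0]}
        res = st.kruskal_dunn(_table(groups), "y")
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no ties
        pooled = np.concatenate(list(groups.values()))
        n_total = pooled.size
        ranks = sps.rankdata(pooled)
        h = 0.0
        start = 0
        for vals in groups.values():
            r = ranks[start:start + len(vals)]
            start += len(vals)
            h += len(vals) * (r.mean() - (n_total + 1) / 2) ** 2
        h *= 12 / (n_total * (n_total + 1))
        assert np.isclose(res.h, h, rtol=1e-12)

    def test_dunn_adjusted_not_below_unadjusted(self):
        rng = np.random.default_rng(6)
        table = _table({g: rng.normal(i, 1, 8)
                        for i, g in enumerate("abc")})
        res = st.kruskal_dunn(table, "y")
        assert (res.pairwise["p_adjusted"]
                >= res.pairwise["p_unadjusted"] - 1e-15).all()

    def test_dunn_flags_separated_group(self):
        rng = np.random.default_rng(7)
        table = _table({"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
                        "c": rng.normal(6, 1, 15)})
        res = st.kruskal_dunn(table, "y")
        pw = res.pairwise.set_index(["contrast_a", "contrast_b"])
        assert pw.loc[("a", "c"), "p_adjusted"] < 0.01
        assert pw.loc[("a", "b"), "p_adjusted"] > 0.05


class TestMannWhitney:
    def test_identical_samples_symmetric_u(self):
        u, _ = st.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == 9 / 2

    def test_complete_separation(self):
        u, _ = st.mann_whitney([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)

    def test_exact_p_matches_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0]
        u_obs, p_obs = st.mann_whitney(a, b)
        # brute force: all C(5,2) assignments of ranks to sample b
        pooled = np.array(a + b)
        n_a = len(a)
        u_null = []
        for idx_a in itertools.combinations(range(5), n_a):
            xa = pooled[list(idx_a)]
            xb = pooled[[i for i in range(5) if i not in idx_a]]
            u = sum((x > y) + 0.5 * (x == y) for x in xa for y in xb)
            u_null.append(u)
        u_null = np.array(u_null)
        mid = len(a) * len(b) / 2
        p_exact = np.mean(np.abs(u_null - mid) >= np.abs(u_obs - mid))
        assert np.isclose(p_obs, p_exact, rtol=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            st.mann_whitney([], [1.0])


class TestChi2Trend:
    def test_identical_proportions_no_trend(self):
        stat, p = st.chi2_trend([5, 10, 15], [10, 20, 30])
        assert np.isclose(stat, 0.0, atol=1e-12)
        assert np.isclose(p, 1.0)

    def test_2x2_equals_pearson_chi2(self):
        r, n = [12, 5], [20, 18]
        stat, _ = st.chi2_trend(r, n)
        table = np.array([[r[0], n[0] - r[0]], [r[1], n[1] - r[1]]])
        expected = sps.chi2_contingency(table, correction=False)[0]
        assert np.isclose(stat, expected, rtol=1e-12)

    def test_matches_hand_formula(self):
        r = np.array([2.0, 6.0, 11.0])
        n = np.array([15.0, 14.0, 16.0])
        x = np.array([0.0, 1.0, 2.0])
        stat, _ = st.chi2_trend(r, n, scores=x)
        p_bar = r.sum() / n.sum()
        num = (x * (r - n * p_bar)).sum() ** 2
        den = p_bar * (1 - p_bar) * (
            (n * x**2).sum() - (n * x).sum() ** 2 / n.sum())
        assert np.isclose(stat, num / den, rtol=1e-14)

    def test_zero_total_group_rejected(self):
        with pytest.raises(InputError):
            st.chi2_trend([1, 0], [5, 0])
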