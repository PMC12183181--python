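"""Edgewise ANOVA, BH-FDR, post-hoc t-tests and summary-statistic tests,
checked against closed forms, scipy cross-checks and null simulations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fcpipe import (
    EdgewiseGroupModel,
    anova_from_summary,
    chi_square_from_counts,
    edgewise_anova,
    fdr_bh,
    posthoc_ttests,
    ttest_from_summary,
)


class TestEdgewiseAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        y = rng.standard_normal((30, 8))
        labels = np.array(["a"] * 14 + ["b"] * 16)
        f, p, _ = edgewise_anova(y, labels)
        t, _ = stats.ttest_ind(y[:14], y[14:], axis=0)
        np.testing.assert_allclose(f, t**2, atol=1e-10)

    def test_hand_fixture_matches_sum_of_squares_oracle(self):
        y = np.array([[1], [3], [2], [4], [5], [7], [6], [8], [9], [11], [10], [12]], float)
        labels = np.repeat(["g1", "g2", "g3"], 4)
        f, p, _ = edgewise_anova(y, labels)
        # textbook SSB/SSW oracle
        grand = y.mean()
        groups = [y[labels == g, 0] for g in ("g1", "g2", "g3")]
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_exp = (ssb / 2) / (ssw / 9)
        assert f[0] == pytest.approx(f_exp, abs=1e-10)
        assert p[0] == pytest.approx(stats.f.sf(f_exp, 2, 9), abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        y = rng.standard_normal((40, 20))
        labels = np.repeat(["a", "b", "c", "d"], 10)
        f, p, _ = edgewise_anova(y, labels)
        f2, p2 = stats.f_oneway(*(y[labels == g] for g in "abcd"), axis=0)
        np.testing.assert_allclose(f, f2, atol=1e-10)
        np.testing.assert_allclose(p, p2, atol=1e-12)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(42)
        y = rng.standard_normal((60, 1000))
        labels = np.repeat(["a", "b", "c"], 20)
        _, p, _ = edgewise_anova(y, labels)
        assert 0.04 <= (p < 0.05).mean() <= 0.06

    def test_constant_feature_flagged_with_p_one(self, rng):
        y = rng.standard_normal((12, 3))
        y[:, 1] = 7.0
        f, p, constant = edgewise_anova(y, np.repeat(["a", "b", "c"], 4))
        assert constant[1] and p[1] == 1.0 and f[1] == 0.0
        assert not constant[[0, 2]].any()

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            edgewise_anova(rng.standard_normal((5, 2)), np.array(["a", "a", "b", "b", "c"]))

    def test_agrees_with_summary_statistic_anova(self, rng):
        y = rng.standard_normal((45, 1)) * 2 + 1
        labels = np.repeat(["a", "b", "c"], 15)
        f, p, _ = edgewise_anova(y, labels)
        means = [y[labels == g].mean() for g in "abc"]
        sds = [y[labels == g].std(ddof=1) for g in "abc"]
        f2, p2 = anova_from_summary(means, sds, [15, 15, 15])
        assert f[0] == pytest.approx(f2, abs=1e-10)
        assert p[0] == pytest.approx(p2, abs=1e-10)


class TestFdrBH:
    def test_uniform_small_p_all_significant(self):
        q, sig = fdr_bh(np.full(10, 0.01))
        assert sig.all() and np.allclose(q, 0.01)

    def test_hand_computed_step_up(self):
        q, sig = fdr_bh(np.array([0.001, 0.013, 0.04, 0.8]))
        np.testing.assert_allclose(q, [0.004, 0.026, 0.04 * 4 / 3, 0.8], atol=1e-12)
        assert sig.tolist() == [True, True, False, False]

    def test_all_ones_none_significant(self):
        q, sig = fdr_bh(np.ones(5))
        assert not sig.any() and (q == 1).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40))
    def test_q_monotone_in_p_ranking(self, ps):
        p = np.array(ps)
        q, _ = fdr_bh(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestPosthoc:
    def test_planted_single_group_shift_pattern(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((60, 1))
        labels = np.repeat(["HAD", "LAD", "HC"], 20)
        y[labels == "HAD"] += 2.0
        out = posthoc_ttests(y, labels, [0])
        pat = out.loc[0, "pattern"]
        assert "HAD>LAD" in pat and "HAD>HC" in pat and "LAD~HC" in pat

    def test_null_pairwise_rate(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((60, 1000))
        labels = np.repeat(["a", "b", "c"], 20)
        out = posthoc_ttests(y, labels, np.arange(1000))
        rates = [(out[c] > 0.05).mean() for c in out.columns if c.startswith("p_")]
        assert all(0.93 <= r <= 0.97 for r in rates)

    def test_minimal_fixture_matches_closed_form(self):
        y = np.array([[1.0], [2.0], [4.0], [7.0]])
        labels = np.array(["a", "a", "b", "b"])
        out = posthoc_ttests(y, labels, [0])
        m1, m2 = 1.5, 5.5
        sp2 = (0.5 + 4.5) / 2
        t_exp = (m1 - m2) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert out.loc[0, "t_a_vs_b"] == pytest.approx(t_exp, abs=1e-12)

    def test_welch_flag_matches_scipy(self, rng):
        y = rng.standard_normal((30, 4))
        labels = np.array(["a"] * 10 + ["b"] * 20)
        out = posthoc_ttests(y, labels, np.arange(4), welch=True)
        t, p = stats.ttest_ind(y[:10], y[10:], axis=0, equal_var=False)
        np.testing.assert_allclose(out["t_a_vs_b"], t, atol=1e-10)
        np.testing.assert_allclose(out["p_a_vs_b"], p, atol=1e-12)


class TestSummaryStatisticTests:
    def test_gender_counts_chi_square(self):
        chi2, p = chi_square_from_counts([[34, 27, 25], [39, 28, 25]])
        assert p == pytest.approx(0.923, abs=0.005)

    def test_proportional_table_is_null(self):
        chi2, p = chi_square_from_counts([[10, 20, 30], [1, 2, 3]])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_two_by_two_matches_expected_counts_oracle(self):
        table = np.array([[10, 20], [20, 10]], float)
        chi2, _ = chi_square_from_counts(table)
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / table.sum()
        assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum(), abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_from_counts([[0, 5], [0, 3]])

    def test_age_row_from_summaries(self):
        _, p = anova_from_summary([34.49, 32.25, 34.06], [9.96, 11.81, 11.22], [73, 55, 50])
        assert p == pytest.approx(0.497, abs=0.01)

    def test_education_row_from_summaries(self):
        _, p = anova_from_summary([11.31, 10.94, 11.44], [3.14, 3.82, 3.69], [73, 55, 50])
        assert p == pytest.approx(0.749, abs=0.01)

    def test_equal_means_give_zero_f(self):
        f, p = anova_from_summary([5, 5, 5], [1, 2, 3], [10, 10, 10])
        assert f == 0.0 and p == 1.0

    def test_equal_summaries_give_zero_t(self):
        t, p = ttest_from_summary(3, 1, 10, 3, 1, 10)
        assert t == 0.0 and p == 1.0

    def test_hamd_row_from_rounded_summaries(self):
        # the printed p reflects unrounded raw data; summaries land nearby
        _, p = ttest_from_summary(20.47, 3.04, 73, 20.16, 4.92, 55)
        assert 0.60 <= p <= 0.72

    def test_pooled_t_matches_closed_form(self):
        t, p = ttest_from_summary(10, 2, 12, 8, 3, 15)
        sp2 = (11 * 4 + 14 * 9) / 25
        t_exp = 2 / np.sqrt(sp2 * (1 / 12 + 1 / 15))
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(t_exp, 25), abs=1e-12)


class TestEdgewiseGroupModel:
    def test_posthoc_only_for_significant_edges(self, rng):
        y = rng.standard_normal((60, 30))
        labels = np.repeat(["a", "b", "c"], 20)
        y[labels == "a", 5] += 3.0
        res = EdgewiseGroupModel(y, labels).fit()
        assert 5 in res.significant_edges
        assert set(res.posthoc["edge"]) == set(res.significant_edges)
        frame = res.to_frame()
        assert frame.loc[5, "significant"]
        # non-significant edges carry no post-hoc values
        other = frame.loc[~frame["significant"], "pattern"]
        assert other.isna().all()

    def test_null_fit_has_empty_posthoc(self, rng):
        y = rng.standard_normal((30, 20))
        res = EdgewiseGroupModel(y, np.repeat(["a", "b", "c"], 10)).fit()
        assert res.posthoc is None or len(res.posthoc) == 0
        assert "significant edges:   0" in res.summary()
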