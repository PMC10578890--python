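"""Tests for the mixed ANOVA, post-hoc contrasts and summary-statistic tests.

The mixed-ANOVA oracle below recomputes every F ratio from cell means and
explicit sums of squares, independently of the implementation route.
"""

import numpy as np
import pytest
from scipy import stats as sps

from pupildyn.stats import (
    InsufficientDataError,
    chi2_2x2_yates,
    chi2_rxc,
    mixed_anova,
    pooled_t_from_summary,
    posthoc_six,
)


def anova_ss_oracle(pre, post, groups):
    """Cell-means sums-of-squares decomposition for the 2x2 mixed design.

    Between-subject: groups tested against subjects-within-groups; within:
    period and interaction tested against the period-by-subject residual.
    """
    pre, post, groups = map(np.asarray, (pre, post, groups))
    labels = np.unique(groups)
    Y = np.column_stack([pre, post])  # subjects x periods
    N, P = Y.shape
    G = len(labels)
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    group_means = {g: Y[groups == g].mean() for g in labels}
    period_means = Y.mean(axis=0)
    cell_means = {(g, j): Y[groups == g, j].mean() for g in labels for j in range(P)}
    n_g = {g: int((groups == g).sum()) for g in labels}

    ss_between = P * sum(n_g[g] * (group_means[g] - grand) ** 2 for g in labels)
    ss_subj = P * sum(
        (subj_means[i] - group_means[groups[i]]) ** 2 for i in range(N)
    )
    ss_period = N * sum((period_means[j] - grand) ** 2 for j in range(P))
    ss_inter = sum(
        n_g[g] * (cell_means[g, j] - group_means[g] - period_means[j] + grand) ** 2
        for g in labels
        for j in range(P)
    )
    ss_err = sum(
        (Y[i, j] - subj_means[i] - cell_means[groups[i], j] + group_means[groups[i]]) ** 2
        for i in range(N)
        for j in range(P)
    )
    df_b, df_s = G - 1, N - G
    df_w = (P - 1, (P - 1) * (N - G))
    F_between = (ss_between / df_b) / (ss_subj / df_s)
    F_period = (ss_period / df_w[0]) / (ss_err / df_w[1])
    F_inter = (ss_inter / (G - 1) / df_w[0]) / (ss_err / df_w[1])
    return F_between, F_period, F_inter


class TestMixedAnova:
    def test_matches_ss_oracle_on_balanced_toy_data(self):
        pre = [3, 5, 4, 9, 8, 10]
        post = [4, 6, 5, 6, 7, 8]
        groups = ["F", "F", "F", "U", "U", "U"]
        res = mixed_anova(pre, post, groups)
        Fb, Fw, Fi = anova_ss_oracle(pre, post, groups)
        assert res.F_between == pytest.approx(Fb, abs=1e-10)
        assert res.F_within == pytest.approx(Fw, abs=1e-10)
        assert res.F_interaction == pytest.approx(Fi, abs=1e-10)

    def test_matches_ss_oracle_on_unbalanced_random_data(self, rng):
        for _ in range(5):
            n1, n2 = 14, 6
            groups = np.array(["F"] * n1 + ["U"] * n2)
            pre = rng.normal(0, 1, n1 + n2) + (groups == "U") * 0.8
            post = pre + rng.normal(0, 0.4, n1 + n2)
            res = mixed_anova(pre, post, groups)
            Fb, Fw, Fi = anova_ss_oracle(pre, post, groups)
            assert res.F_between == pytest.approx(Fb, rel=1e-8)
            assert res.F_within == pytest.approx(Fw, rel=1e-8)
            assert res.F_interaction == pytest.approx(Fi, rel=1e-8)

    def test_between_f_equals_squared_t_on_subject_means(self, rng):
        groups = np.array(["F"] * 9 + ["U"] * 5)
        pre = rng.normal(size=14)
        post = rng.normal(size=14)
        res = mixed_anova(pre, post, groups)
        means = (pre + post) / 2
        t, _ = sps.ttest_ind(means[groups == "F"], means[groups == "U"], equal_var=True)
        assert res.F_between == pytest.approx(t**2, rel=1e-8)

    def test_invariance_to_order_and_constant_shift(self, rng):
        groups = np.array(["F"] * 6 + ["U"] * 4)
        pre, post = rng.normal(size=10), rng.normal(size=10)
        base = mixed_anova(pre, post, groups)
        perm = rng.permutation(10)
        shuffled = mixed_anova(pre[perm], post[perm], groups[perm])
        shifted = mixed_anova(pre + 17.0, post + 17.0, groups)
        for other in (shuffled, shifted):
            assert other.F_between == pytest.approx(base.F_between, rel=1e-8)
            assert other.F_interaction == pytest.approx(base.F_interaction, rel=1e-8)

    def test_zero_variance_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            res = mixed_anova([1.0] * 6, [1.0] * 6, ["F"] * 3 + ["U"] * 3)
        assert np.isnan(res.F_between) or res.F_between == 0.0

    def test_insufficient_group_raises(self):
        with pytest.raises(InsufficientDataError):
            mixed_anova([1, 2, 3], [1, 2, 3], ["F", "F", "U"])

    def test_permutation_oracle_on_default_cohort(self, default_cohort, rng):
        """The real group labels produce a between-group F above the 95th
        percentile of 500 label permutations."""
        from pupildyn.indices import cohort_prepost_table

        tab = cohort_prepost_table(default_cohort)
        wide = tab.pivot_table(index=["patient_id", "outcome"], columns="period")
        pre = wide[("ps_isochoria_pct", "pre")].to_numpy()
        post = wide[("ps_isochoria_pct", "post")].to_numpy()
        groups = wide.index.get_level_values("outcome").to_numpy()
        real = mixed_anova(pre, post, groups).F_between
        null = []
        for _ in range(500):
            null.append(anova_ss_oracle(pre, post, rng.permutation(groups))[0])
        assert real > np.quantile(null, 0.95)


class TestPosthoc:
    def test_identical_groups_all_corrected_ps_capped_at_one(self, rng):
        x = rng.normal(size=10)
        res = posthoc_six(x, x + rng.normal(0, 1e-12, 10), ["FAVORABLE"] * 5 + ["UNFAVORABLE"] * 5)
        # identical group distributions: nothing should survive correction
        for r in res[:2] + res[4:5]:
            assert r.p_bonferroni == pytest.approx(1.0, abs=0.2)

    def test_exactly_six_comparisons_and_monotone_correction(self, rng):
        pre, post = rng.normal(size=12), rng.normal(size=12)
        res = posthoc_six(pre, post, ["FAVORABLE"] * 8 + ["UNFAVORABLE"] * 4)
        assert len(res) == 6
        for r in res:
            assert r.p_bonferroni >= r.p_raw
            assert r.p_bonferroni == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_paired_t_matches_textbook_formula(self):
        pre = np.array([0.6, 0.5, 0.8, 0.7])
        post = np.array([0.4, 0.45, 0.5, 0.6])
        res = posthoc_six(
            np.concatenate([pre, [0.3, 0.2]]),
            np.concatenate([post, [0.25, 0.15]]),
            ["FAVORABLE"] * 4 + ["UNFAVORABLE"] * 2,
        )
        d = pre - post
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        fav_paired = next(r for r in res if r.comparison == "F_pre vs F_post")
        assert fav_paired.t == pytest.approx(t_expected)


class TestSummaryTests:
    def test_age_pooled_t_reproduces_reference_cohort(self):
        """Printed group summaries (43.06+-16.15, n=15 vs 46+-23.12, n=6)."""
        # summaries are themselves rounded, so allow one unit in the last place
        t, p = pooled_t_from_summary(43.06, 16.15, 15, 46.0, 23.12, 6)
        assert abs(t) == pytest.approx(0.333, abs=1e-3)
        assert p == pytest.approx(0.743, abs=1e-3)

    def test_equal_means_gives_zero_t(self):
        t, p = pooled_t_from_summary(5, 1, 10, 5, 2, 10)
        assert t == 0.0 and p == 1.0

    def test_zero_variance_unequal_means_flagged_infinite(self):
        t, p = pooled_t_from_summary(5, 0, 10, 4, 0, 10)
        assert np.isinf(t) and p == 0.0

    def test_closed_form_check(self):
        t, _ = pooled_t_from_summary(10, 6, 15, 8, 7, 6)
        sp2 = (14 * 36 + 5 * 49) / 19
        assert t == pytest.approx(2 / np.sqrt(sp2 * (1 / 15 + 1 / 6)))

    @pytest.mark.parametrize(
        "counts,chi2_expected,p_expected",
        [
            ((12, 3, 0, 6), 8.17, 0.004),   # tSAH
            ((5, 10, 0, 6), 1.11, None),    # EDH
            ((0, 15, 1, 5), 0.24, None),    # IVH
            ((3, 12, 3, 3), 0.71, 0.40),    # neurosurgery
            ((10, 5, 5, 1), 0.05, 0.81),    # invasive neuromonitoring
        ],
    )
    def test_yates_chi2_reproduces_reference_cohort(self, counts, chi2_expected, p_expected):
        chi2, p = chi2_2x2_yates(*counts)
        assert chi2 == pytest.approx(chi2_expected, abs=5e-3)
        if p_expected is not None:
            # p-values are printed to 2-3 decimals; match to that precision
            assert p == pytest.approx(p_expected, abs=0.01)

    def test_yates_correction_floor(self):
        chi2, p = chi2_2x2_yates(5, 5, 5, 5)
        assert chi2 == 0.0 and p == 1.0

    def test_yates_never_exceeds_uncorrected(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 30, size=4)
            corrected, _ = chi2_2x2_yates(a, b, c, d)
            uncorrected, _, _ = chi2_rxc([[a, b], [c, d]])
            assert corrected <= uncorrected + 1e-12

    def test_marshall_rxc_reproduces_reference_cohort(self):
        chi2, df, p = chi2_rxc([[10, 2, 1, 2], [1, 3, 2, 0]])
        assert chi2 == pytest.approx(7.40, abs=5e-3)
        assert df == 3
        assert p == pytest.approx(0.06, abs=5e-3)

    def test_rxc_independence_gives_zero(self):
        table = np.outer([2, 3], [4, 5, 6])
        chi2, df, p = chi2_rxc(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_2x2_uncorrected_matches_algebraic_identity(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            chi2, _, _ = chi2_rxc([[a, b], [c, d]])
            assert chi2 == pytest.approx(expected)

    def test_chi2_matches_scipy_cross_check(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
            ours, p_ours = chi2_2x2_yates(a, b, c, d)
            ref, p_ref, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=True)
            assert ours == pytest.approx(ref) and p_ours == pytest.approx(p_ref)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError):
            chi2_2x2_yates(0, 0, 3, 4)
        with pytest.raises(ValueError):
            chi2_rxc([[0, 0], [3, 4]])
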