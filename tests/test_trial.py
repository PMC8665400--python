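"""Trial-level analytics: baseline tests, mixed model, effect sizes, PPV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import megclust as mc
from megclust.trial import cohort_to_long, cutoff_respondents


class TestTwoSampleT:
    def test_study_age_comparison(self):
        t, df, p = mc.two_sample_t((9.2, 1.21, 15), (9.71, 1.33, 14))
        assert df == 27
        assert round(abs(t), 2) == 1.08  # printed as 1.09 from unrounded data
        assert abs(abs(t) - 1.09) < 0.02
        assert 0.2 < p < 0.35

    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = mc.two_sample_t(a, a.copy())
        assert t == 0.0 and p == 1.0

    def test_shifted_sample_matches_pooled_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = a + 1.0
        t, df, p = mc.two_sample_t(a, b)
        # pooled sd = 1, se = 1*sqrt(2/3)
        assert t == pytest.approx(-1.0 / np.sqrt(2.0 / 3.0))
        assert df == 4

    def test_welch_variant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 3, 25)
        t, df, p = mc.two_sample_t(a, b, welch=True)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)


class TestChiSquare:
    def test_study_medication_table(self):
        chi2, df, p = mc.chi_square_2x2([[9, 6], [11, 3]])
        assert round(chi2, 2) == 1.17
        assert 0.25 < p < 0.31

    def test_study_psych_treatment_table(self):
        chi2, _, p = mc.chi_square_2x2([[4, 11], [3, 11]])
        assert round(chi2, 2) == 0.11
        assert 0.70 < p < 0.78

    def test_proportional_table_is_zero(self):
        chi2, _, p = mc.chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            mc.chi_square_2x2([[0, 0], [3, 4]])

    @pytest.mark.parametrize("seed", range(5))
    def test_shortcut_equals_observed_vs_expected_sum(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 40, size=(2, 2)).astype(float)
        chi2, _, _ = mc.chi_square_2x2(t)
        expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
        direct = ((t - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(direct, abs=1e-12)
        ref = stats.chi2_contingency(t, correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)


class TestMixedModel:
    def _long(self, pre, post, ne):
        n = len(pre)
        ids = [f"S{i:03d}" for i in range(n)]
        arm = ["experimental"] * ne + ["control"] * (n - ne)
        return pd.DataFrame(
            {
                "participant_id": ids * 2,
                "arm": arm * 2,
                "period": ["pre"] * n + ["post"] * n,
                "score": np.concatenate([pre, post]),
            }
        )

    def test_no_change_gives_exactly_zero_interaction(self):
        rng = np.random.default_rng(1)
        pre = rng.normal(50, 8, 29)
        res = mc.fit_prepost_mixed_model(self._long(pre, pre.copy(), 15))
        assert res.beta_interaction == 0.0
        assert res.degenerate

    def test_interaction_sign_follows_planted_effect(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(0, 1, 29)
        post = pre + rng.normal(0, 0.5, 29)
        post[:15] += 1.0
        res = mc.fit_prepost_mixed_model(self._long(pre, post, 15),
                                         age_covariate="never")
        assert res.beta_interaction > 0.5
        assert res.p < 0.05
        assert res.lr_chi2 > 0

    def test_small_arm_rejected(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(0, 1, 6)
        long = self._long(pre, pre + 0.1, 2)
        with pytest.raises(ValueError, match="fewer than 3"):
            mc.fit_prepost_mixed_model(long)

    def test_cohort_to_long_shapes(self, default_cohort):
        long = cohort_to_long(default_cohort)
        assert len(long) == 58
        assert set(long.period) == {"pre", "post"}


class TestEffectSizes:
    def test_control_arm_summary_moments_give_printed_g(self):
        # reconstruct samples with exactly the printed control moments
        def with_moments(m, s, n, seed):
            x = np.random.default_rng(seed).normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return m + s * x

        pre = with_moments(48.79, 7.53, 14, 0)
        post = with_moments(49.64, 7.32, 14, 1)
        g = mc.hedges_g_prepost(pre, post)
        assert g == pytest.approx(0.1077, abs=5e-4)
        assert round(g, 1) == 0.1

    def test_no_change_gives_zero(self):
        x = np.array([3.0, 4.0, 5.0])
        assert mc.hedges_g_prepost(x, x.copy()) == 0.0

    def test_matches_hand_computed_formula(self):
        pre = np.array([1.0, 2.0, 3.0, 4.0])
        post = np.array([2.0, 2.5, 4.0, 5.5])
        s_avg = np.sqrt((np.var(pre, ddof=1) + np.var(post, ddof=1)) / 2)
        expected = (1 - 3 / 11) * (post.mean() - pre.mean()) / s_avg
        assert mc.hedges_g_prepost(pre, post) == pytest.approx(expected)

    def test_sign_flips_when_swapped(self):
        rng = np.random.default_rng(5)
        pre, post = rng.normal(size=10), rng.normal(size=10) + 1
        assert mc.hedges_g_prepost(pre, post) == pytest.approx(
            -mc.hedges_g_prepost(post, pre)
        )


class TestRespondents:
    def test_no_change_no_respondents(self):
        x = np.arange(10.0) + 40
        assert mc.respondent_analysis(x, x.copy(), 0.64, sd_ref=8.0) == (0, 0.0)

    def test_boundary_is_inclusive(self):
        pre = np.full(5, 50.0)
        post = pre - 0.64 * 8.0
        count, frac = mc.respondent_analysis(pre, post, 0.64, sd_ref=8.0)
        assert (count, frac) == (5, 1.0)

    def test_eight_of_fifteen_fixture(self):
        # mirror the study's experimental-arm respondent proportion 8/15
        sd_ref = 8.0
        pre = np.full(15, 55.0)
        post = pre.copy()
        post[:8] -= 0.7 * sd_ref  # clear respondents
        post[8:] -= 0.2 * sd_ref  # improved, below threshold
        count, frac = mc.respondent_analysis(pre, post, 0.64, sd_ref=sd_ref)
        assert count == 8
        assert frac == pytest.approx(8 / 15)

    def test_bad_sd_rejected(self):
        with pytest.raises(ValueError, match="sd_ref"):
            mc.respondent_analysis([1.0, 2.0], [1.0, 2.0], 0.64, sd_ref=0.0)

    def test_cutoff_respondents(self):
        count, frac = cutoff_respondents([28, 35, 25, 31], 30, "below")
        assert (count, frac) == (2, 0.5)


class TestPPV:
    def test_study_value(self):
        assert round(mc.ppv(0.43, 0.05, 0.5), 2) == 0.81
        assert mc.ppv(0.43, 0.05, 0.5) == pytest.approx(0.81132, abs=1e-5)

    def test_alpha_to_zero_limit(self):
        assert mc.ppv(0.5, 1e-12, 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_direct_formula_point(self):
        assert mc.ppv(0.8, 0.05, 0.5) == pytest.approx(0.888888, abs=1e-5)

    def test_monotonicity(self):
        base = mc.ppv(0.4, 0.05, 0.5)
        assert mc.ppv(0.5, 0.05, 0.5) > base
        assert mc.ppv(0.4, 0.05, 0.8) > base
        assert mc.ppv(0.4, 0.1, 0.5) < base

    def test_invalid_inputs(self):
        for bad in [(0.0, 0.05, 0.5), (0.4, 0.0, 0.5), (0.4, 0.05, 0.0)]:
            with pytest.raises(ValueError):
                mc.ppv(*bad)


class TestPairedT:
    def test_matches_scipy_and_closed_form(self):
        rng = np.random.default_rng(8)
        pre = rng.normal(50, 8, 15)
        post = pre + rng.normal(-3, 4, 15)
        t, df, p = mc.paired_t(pre, post)
        ref = stats.ttest_rel(post, pre)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        d = post - pre
        assert t == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(15)))

    def test_constant_shift_degenerate(self):
        pre = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            mc.paired_t(pre, pre + 2.0)

    def test_sign_follows_shift_with_noise(self):
        rng = np.random.default_rng(9)
        pre = rng.normal(size=20)
        t_up, *_ = mc.paired_t(pre, pre + 2 + rng.normal(0, 0.1, 20))
        t_dn, *_ = mc.paired_t(pre, pre - 2 + rng.normal(0, 0.1, 20))
        assert t_up > 0 > t_dn

    def test_bonferroni_factor_is_per_family(self):
        fams = {
            "BRIEF": {f"s{i}": 0.01 for i in range(4)},
            "EDAH": {f"s{i}": 0.02 for i in range(4)},
        }
        adj = mc.bonferroni_families(fams)
        assert adj["BRIEF"]["s0"] == pytest.approx(0.04)  # factor 4, not 8
        assert adj["EDAH"]["s0"] == pytest.approx(0.08)


class TestTrialOutcomeModel:
    def test_fit_produces_consistent_report(self, default_cohort):
        res = mc.TrialOutcomeModel(default_cohort).fit()
        assert set(res.hedges_g) == {"experimental", "control"}
        # generator plants an improvement in the experimental arm only
        assert res.hedges_g["experimental"] < 0
        assert res.respondents["experimental"][0] >= res.respondents["control"][0]
        assert len(res.baseline) == 4
        text = res.summary()
        assert "Mixed model" in text and "Hedges g" in text

    def test_baseline_table_recovers_counts(self, default_cohort):
        table = mc.baseline_table(default_cohort)
        med = table[table.characteristic == "Using medication"].iloc[0]
        n_med = int(default_cohort.data["medicated"].sum())
        assert med.experimental.startswith(
            str(int(default_cohort.data.loc[
                default_cohort.arm_mask("experimental"), "medicated"].sum()))
        )
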