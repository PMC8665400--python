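"""The synthetic generator: determinism, study-condition moments, planted effect."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

import megclust as mc


class TestSourceSpace:
    def test_deterministic_coordinates(self):
        a = mc.generate_source_space(1200, 10, 7)
        b = mc.generate_source_space(1200, 10, 7)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.edges, b.edges)

    def test_27_nodes_form_a_cube(self, cube27):
        c = cube27.coords
        assert sorted(set(c[:, 0])) == [-10.0, 0.0, 10.0]
        assert len(c) == 27
        assert cube27.degree().max() == 6

    def test_one_percent_of_default_grid_is_twelve(self):
        g = mc.generate_source_space(1200, 10, 0)
        assert int(np.ceil(0.01 * g.n_nodes)) == 12

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match=">= 27"):
            mc.generate_source_space(10, 10, 0)


class TestClinicalCohort:
    def test_sample_moments_near_study_conditions(self):
        # averaged over replicates the arm means must sit within 3 standard
        # errors of the configured baselines (53.87 / 48.79)
        means_e, means_c = [], []
        for seed in range(20):
            c = mc.generate_clinical_cohort(mc.CohortSpec(seed=seed))
            df = c.data
            means_e.append(df.loc[c.arm_mask("experimental"),
                                  "cpt_commission_pre"].mean())
            means_c.append(df.loc[c.arm_mask("control"),
                                  "cpt_commission_pre"].mean())
        se_e = 8.37 / np.sqrt(15 * 20)
        se_c = 7.53 / np.sqrt(14 * 20)
        assert abs(np.mean(means_e) - 53.87) < 3 * se_e
        assert abs(np.mean(means_c) - 48.79) < 3 * se_c

    def test_zero_noise_zero_effect_post_equals_pre(self):
        spec = mc.CohortSpec(residual_sd=0.0, arm_effect=(0.0, 0.0), seed=4)
        c = mc.generate_clinical_cohort(spec)
        assert np.array_equal(
            c.data["cpt_commission_pre"], c.data["cpt_commission_post"]
        )

    def test_single_participant_arm_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mc.CohortSpec(n_experimental=1)

    def test_ages_within_range(self, default_cohort):
        lo, hi = default_cohort.age_range
        assert default_cohort.ages.min() >= lo
        assert default_cohort.ages.max() <= hi


class TestPlantedEffect:
    def test_zero_noise_ratio_is_exact(self, small_graph, default_cohort):
        fa = mc.make_freq_axis(8.0, 16.0)
        effect = mc.EffectSpec(target_rho=0.0, noise_sd_log_ratio=0.0)
        pre, post, truth = mc.generate_power_data(
            default_cohort, small_graph, effect, fa, seed=1
        )
        ratio = mc.compute_ratio_tensor(pre, post)
        assert np.allclose(ratio.values, 1.0)

    def test_zero_noise_with_effect_is_closed_form(self, small_graph,
                                                   default_cohort):
        fa = mc.make_freq_axis(8.0, 16.0)
        with pytest.warns(UserWarning, match="unreachable"):
            effect = mc.EffectSpec(target_rho=-0.56, noise_sd_log_ratio=0.0)
            pre, post, truth = mc.generate_power_data(
                default_cohort, small_graph, effect, fa, seed=1
            )
        ratio = mc.compute_ratio_tensor(pre, post).values
        cpt = mc.compute_cpt_ratio(default_cohort)
        z = (cpt - cpt.mean()) / cpt.std(ddof=0)
        nodes = np.asarray(truth.nodes)
        s0, s1 = truth.step_span
        expected = np.exp(-0.05 * z)  # the deterministic fallback slope
        inside = ratio[:, nodes][:, :, s0 : s1 + 1]
        assert np.allclose(inside, expected[:, None, None])
        outside_node = next(
            v for v in range(small_graph.n_nodes) if v not in set(truth.nodes)
        )
        assert np.allclose(ratio[:, outside_node, :], 1.0)

    def test_null_effect_leaves_ratio_distributions_matched(self, small_graph,
                                                            default_cohort):
        fa = mc.make_freq_axis(8.0, 16.0)
        effect = mc.EffectSpec(target_rho=0.0)
        pre, post, truth = mc.generate_power_data(
            default_cohort, small_graph, effect, fa, seed=2
        )
        ratio = mc.compute_ratio_tensor(pre, post).values
        nodes = np.asarray(truth.nodes)
        s0, s1 = truth.step_span
        inside = ratio[:, nodes][:, :, s0 : s1 + 1].ravel()
        mask = np.ones(small_graph.n_nodes, bool)
        mask[nodes] = False
        outside = ratio[:, mask][:, :, s0 : s1 + 1].ravel()
        rng = np.random.default_rng(0)
        ks = stats.ks_2samp(
            rng.choice(inside, 29, replace=False),
            rng.choice(outside, 29, replace=False),
        )
        assert ks.pvalue > 0.01

    def test_calibration_hits_target_on_average(self, small_graph):
        # Monte-Carlo check of the Spearman calibration: mean realized
        # (age-partialed) correlation within +/-0.12 of the -0.56 target
        fa = mc.make_freq_axis(8.0, 16.0)
        achieved = []
        for seed in range(50):
            cohort = mc.generate_clinical_cohort(mc.CohortSpec(seed=100 + seed))
            _, _, truth = mc.generate_power_data(
                cohort, small_graph, mc.EffectSpec(), fa, seed=200 + seed
            )
            achieved.append(truth.achieved_rho)
        assert abs(np.mean(achieved) - (-0.56)) < 0.12

    def test_band_outside_axis_rejected(self, small_graph, default_cohort):
        fa = mc.make_freq_axis(2.0, 8.0)
        with pytest.raises(ValueError, match="band"):
            mc.generate_power_data(
                default_cohort, small_graph, mc.EffectSpec(), fa, seed=0
            )


class TestDatasetDeterminism:
    def test_identical_seed_gives_byte_identical_dataset(self, tmp_path):
        dirs = []
        for name in ("a", "b"):
            cohort, pre, post, graph, truth = mc.simulate_dataset(
                n_nodes=60, freq_axis=mc.make_freq_axis(8.0, 14.0), seed=5
            )
            out = mc.write_dataset(tmp_path / name, cohort, pre, post, graph,
                                   truth=truth, seed=5)
            dirs.append(out)
        files = sorted(p.relative_to(dirs[0]) for p in dirs[0].rglob("*")
                       if p.is_file())
        assert files
        for rel in files:
            assert (dirs[1] / rel).is_file()
            assert filecmp.cmp(dirs[0] / rel, dirs[1] / rel, shallow=False), rel
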