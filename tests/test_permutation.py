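"""Max-statistic permutation inference: p-value rules, determinism, oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

import megclust as mc
from megclust.cluster import permutation_test
from megclust.datatypes import ClusterParams, RatioTensor
from oracles import brute_max_mass


@pytest.fixture(scope="module")
def strong_inference(planted_dataset):
    cohort, pre, post, graph, truth = planted_dataset
    ratio = mc.compute_ratio_tensor(pre, post)
    params = ClusterParams(n_permutations=500, seed=5)
    return permutation_test(
        ratio, mc.compute_cpt_ratio(cohort), cohort.ages, graph, params
    )


class TestPermutationBasics:
    def test_observed_mass_beyond_null_gives_plus_one_rule_p(
        self, strong_inference
    ):
        inf = strong_inference
        top = int(np.argmax([abs(c.mass) for c in inf.clusters]))
        assert abs(inf.clusters[top].mass) > inf.null_max_mass.max()
        assert inf.p_values[top] == pytest.approx(1.0 / 501.0)

    def test_deterministic_under_seed(self, planted_dataset):
        cohort, pre, post, graph, truth = planted_dataset
        ratio = mc.compute_ratio_tensor(pre, post)
        cpt = mc.compute_cpt_ratio(cohort)
        params = ClusterParams(n_permutations=150, seed=9)
        a = permutation_test(ratio, cpt, cohort.ages, graph, params)
        b = permutation_test(ratio, cpt, cohort.ages, graph, params)
        assert np.array_equal(a.null_max_mass, b.null_max_mass)
        assert np.array_equal(a.p_values, b.p_values)
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]

    def test_doubling_permutations_keeps_observed_clusters(self, planted_dataset):
        cohort, pre, post, graph, truth = planted_dataset
        ratio = mc.compute_ratio_tensor(pre, post)
        cpt = mc.compute_cpt_ratio(cohort)
        a = permutation_test(ratio, cpt, cohort.ages, graph,
                             ClusterParams(n_permutations=100, seed=1))
        b = permutation_test(ratio, cpt, cohort.ages, graph,
                             ClusterParams(n_permutations=200, seed=2))
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]
        assert [c.mass for c in a.clusters] == [c.mass for c in b.clusters]

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="100"):
            ClusterParams(n_permutations=50)

    def test_joint_shuffle_mode_runs(self, planted_dataset):
        cohort, pre, post, graph, truth = planted_dataset
        ratio = mc.compute_ratio_tensor(pre, post)
        params = ClusterParams(n_permutations=100, seed=3, shuffle="joint")
        inf = permutation_test(ratio, mc.compute_cpt_ratio(cohort),
                               cohort.ages, graph, params)
        assert inf.null_max_mass.size == 100


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle at n = 6


@pytest.fixture(scope="module")
def tiny_problem(line_graph):
    rng = np.random.default_rng(12)
    n, nv, ns = 6, 3, 8
    vals = rng.lognormal(sigma=0.1, size=(n, nv, ns))
    y = np.array([0.70, 0.85, 0.95, 1.00, 1.05, 1.20])
    # couple nodes 0-1, steps 2-6 to y so an observed cluster exists
    for v in (0, 1):
        for s in range(2, 7):
            vals[:, v, s] *= np.exp(-0.8 * (y - 1.0))
    z = rng.uniform(8, 11, size=n)
    ratio = RatioTensor(vals, 8.0 + np.arange(ns) / 3.0,
                        [f"P{i}" for i in range(n)])
    params = ClusterParams(alpha_node=0.3, min_consecutive_steps=2,
                           min_extent_fraction=0.0, n_permutations=500,
                           seed=21)
    return ratio, y, z, params


@pytest.fixture(scope="module")
def oracle_null(tiny_problem, line_graph):
    ratio, y, z, params = tiny_problem
    return np.asarray(
        [
            brute_max_mass(ratio.values, y[list(perm)], z, line_graph.edges,
                           params.alpha_node, params.min_consecutive_steps)
            for perm in itertools.permutations(range(6))
        ]
    )


class TestExhaustiveOracle:
    def test_monte_carlo_p_matches_exhaustive_enumeration(
        self, tiny_problem, line_graph, oracle_null
    ):
        ratio, y, z, params = tiny_problem
        mc_inf = permutation_test(ratio, y, z, line_graph, params)
        assert mc_inf.clusters, "fixture must produce an observed cluster"
        top = int(np.argmax([abs(c.mass) for c in mc_inf.clusters]))
        obs_mass = abs(mc_inf.clusters[top].mass)
        p_exact = (np.count_nonzero(oracle_null >= obs_mass - 1e-12) + 1) / 721
        p_mc = mc_inf.p_values[top]
        assert abs(p_mc - p_exact) <= 2 / np.sqrt(720)

    def test_explicit_full_permutation_group_reproduces_oracle(
        self, tiny_problem, line_graph, oracle_null
    ):
        ratio, y, z, params = tiny_problem
        orders = np.array(list(itertools.permutations(range(6))))
        inf = permutation_test(ratio, y, z, line_graph, params, orders=orders)
        assert np.allclose(np.sort(inf.null_max_mass), np.sort(oracle_null),
                           atol=1e-9)


class TestNullPValueCalibration:
    def test_top_cluster_p_is_uniform_under_exchangeability(self):
        # permissive filters so a top cluster exists in every replicate;
        # its p must then be (discretely) uniform by exchangeability
        rng = np.random.default_rng(77)
        coords = np.column_stack([np.arange(8) * 10.0, np.zeros(8), np.zeros(8)])
        graph = mc.build_spatial_adjacency(coords, d_max=10.5)
        params = ClusterParams(alpha_node=0.6, min_consecutive_steps=1,
                               min_extent_fraction=0.0, n_permutations=150)
        pvals = []
        for rep in range(60):
            vals = rng.lognormal(sigma=0.2, size=(12, 8, 6))
            ratio = RatioTensor(vals, 8.0 + np.arange(6) / 3.0,
                                [f"P{i}" for i in range(12)])
            y = rng.uniform(0.7, 1.3, 12)
            z = rng.uniform(8, 11, 12)
            p = ClusterParams(alpha_node=0.6, min_consecutive_steps=1,
                              min_extent_fraction=0.0, n_permutations=150,
                              seed=rep)
            inf = permutation_test(ratio, y, z, graph, p)
            if inf.clusters:
                pvals.append(inf.p_values.min())
        assert len(pvals) >= 50
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001
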