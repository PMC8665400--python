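import numpy as np
import pytest

import megclust as mc


@pytest.fixture(scope="session")
def cube27():
    """3x3x3 regular grid at 10 mm spacing."""
    return mc.generate_source_space(27, 10, 1)


@pytest.fixture(scope="session")
def small_graph():
    """120-node head-like grid used by mid-size tests."""
    return mc.generate_source_space(120, 10, 0)


@pytest.fixture(scope="session")
def default_cohort():
    return mc.generate_clinical_cohort(mc.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def planted_dataset(default_cohort):
    """300-node dataset with a strong planted alpha-band cluster."""
    graph = mc.generate_source_space(300, 10, 0)
    freq_axis = mc.make_freq_axis(8.0, 16.0)
    pre, post, truth = mc.generate_power_data(
        default_cohort, graph, mc.EffectSpec(target_rho=-0.6), freq_axis, seed=3
    )
    return default_cohort, pre, post, graph, truth


@pytest.fixture(scope="session")
def line_graph():
    """Three collinear nodes 10 mm apart: edges (0,1) and (1,2) only."""
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0], [20.0, 0, 0]])
    return mc.build_spatial_adjacency(coords, d_max=12.0)
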