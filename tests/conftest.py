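import numpy as np
import pytest

from geoadd.synthetic import (
    SimulationConfig,
    default_truth,
    make_fixture_graph,
    simulate_survey,
)


@pytest.fixture(scope="session")
def graph():
    return make_fixture_graph()


@pytest.fixture(scope="session")
def small_survey(graph):
    """A small simulated survey (n=500) with its generating truth."""
    truth = default_truth(graph, seed=11, prevalence_target=0.2)
    cfg = SimulationConfig(n=500, graph=graph, seed=11, prevalence_target=0.2)
    table, truth = simulate_survey(cfg, truth)
    return table, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
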