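import numpy as np
import pytest

from richclubnet.io import AnalysisConfig
from richclubnet.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (smaller groups) for fast pipeline exercises."""
    cfg = SimulationConfig(n_per_group=(5, 6, 7), n_nodes=30, n_hubs=5,
                          nbs_n_edges=8, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def analysis_config():
    return AnalysisConfig(seed=3)


def complete_graph(n, weight=1.0):
    w = np.full((n, n), weight, dtype=float)
    np.fill_diagonal(w, 0.0)
    return w
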