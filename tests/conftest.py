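import numpy as np
import pytest

from ncruv.core_data import ControlMask, LogExpressionMatrix, make_replicate_design
from ncruv.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_experiment():
    """A compact simulated experiment shared by I/O and normalization tests."""
    config = SimulationConfig(
        m_bio=11, n_genes=30, n_hk=3, n_de=5, n_batches=2, seed=3
    )
    return simulate(config)


@pytest.fixture(scope="session")
def codeset_experiment():
    """The three-batch spanning-replicate study used for recovery checks."""
    from ncruv.simulate import scenario_presets

    return simulate(scenario_presets()["codeset_batches"])


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_log_matrix(rng, m, n, loc=8.0, scale=1.0):
    vals = rng.normal(loc, scale, size=(m, n))
    return LogExpressionMatrix(
        vals, [f"s{i}" for i in range(m)], [f"g{j}" for j in range(n)]
    )


@pytest.fixture()
def all_controls():
    def _make(n):
        return ControlMask(np.ones(n, dtype=bool), source="all_genes")

    return _make


@pytest.fixture()
def paired_design():
    """8 assays, 4 biological samples, every sample assayed twice."""
    ids = [f"s{i}" for i in range(8)]
    bio = ["a", "a", "b", "b", "c", "c", "d", "d"]
    return make_replicate_design(ids, bio)
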