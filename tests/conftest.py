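import numpy as np
import pytest

from connectoprint.synthetic import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study under the standard conditions (seed 0)."""
    return generate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def rest_matrix(default_study):
    return default_study.population_matrix("rest")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides) -> SimulationConfig:
    """A quick-to-generate study for tests that loop over many seeds."""
    base = dict(
        n_subjects=30,
        n_regions=20,
        n_signature_edges=15,
        n_drift_edges=8,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
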