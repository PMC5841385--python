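import numpy as np
import pytest

from polyqevo.simulate import SimConfig, simulate_dataset, worked_example_fixture


@pytest.fixture(scope="session")
def worked_group():
    group, divergence = worked_example_fixture()
    return group, divergence


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic data set shared across tests (read-only)."""
    return simulate_dataset(SimConfig(seed=11, n_groups=40, n_panel=4))


@pytest.fixture(scope="session")
def small_data_dir(small_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("simdata")
    small_sim.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
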