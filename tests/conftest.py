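import warnings

import pytest

from methlink.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig.small(seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small synthetic study shared across the suite (seeded)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_dataset):
    outdir = tmp_path_factory.mktemp("small_data")
    write_dataset(small_dataset, outdir)
    return outdir
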