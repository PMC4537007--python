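import numpy as np
import pytest

from mirmodscore import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def small_config():
    """A small, fast experiment with one module of 5 miRs and 10 targets."""
    return SimulationConfig(
        n_mirs=30, n_mrnas=60, n_modules=1,
        mirs_per_module=(5,), targets_per_module=(10,),
        effect_size_log2=((1.5, 1.0, 0.5),),
        noise_sd=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def experiment(default_config):
    return simulate_experiment(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
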