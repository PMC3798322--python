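import numpy as np
import pytest

from metamodule import SimConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Four modest cohorts with a 10-gene module and a prognostic seed gene."""
    return SimConfig(
        n_cohorts=4,
        samples_per_cohort=[120, 150, 130, 140],
        n_genes=60,
        module_size=10,
        module_loading=float(np.sqrt(0.7)),
        prognostic_genes={"G0001": 0.5},
        noise_sd=[1.0, 0.8, 1.2, 0.9],
        seed=123,
    )


@pytest.fixture(scope="session")
def small_bundles(small_config):
    return simulate_cohorts(small_config)
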