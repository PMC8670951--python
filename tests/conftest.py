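import numpy as np
import pytest

from axialgrowth.data_model import stage_summaries
from axialgrowth.synthetic_data import SimulationConfig, simulate_ontogeny

#: Generating parameter sets used across tests for parameter-recovery and
#: model-selection checks (noise-free structural RSS separates the models).
SGA_PARAMS = {"A": 0.12, "B": 0.8, "k": 0.85, "k_slope": 0.0}
TGT_PARAMS = {"c0": 0.4, "c1": 3.0, "q0": 0.54, "q1": 0.835}
TGT_SCHEDULE = {"gamma": 0.5, "delta": 0.30}


@pytest.fixture(scope="session")
def zero_noise_specs():
    cfg = SimulationConfig(seed=1, sigma_size=0.0, sigma_part=0.0)
    return simulate_ontogeny(cfg)


@pytest.fixture(scope="session")
def zero_noise_summaries(zero_noise_specs):
    return stage_summaries(zero_noise_specs)


@pytest.fixture(scope="session")
def noisy_specs():
    return simulate_ontogeny(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sga_zero_noise_summaries():
    cfg = SimulationConfig(seed=3, sigma_size=0.0, sigma_part=0.0,
                           gradient_model="SG-A", gradient_params=SGA_PARAMS,
                           pygidium_mode="gradient")
    return stage_summaries(simulate_ontogeny(cfg))


@pytest.fixture(scope="session")
def tgt_zero_noise_summaries():
    cfg = SimulationConfig(seed=3, sigma_size=0.0, sigma_part=0.0,
                           gradient_model="TG-T", gradient_params=TGT_PARAMS,
                           pygidium_mode="gradient", **TGT_SCHEDULE)
    return stage_summaries(simulate_ontogeny(cfg))
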