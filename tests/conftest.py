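import numpy as np
import pytest

from lactoflow import SimConfig, TurnoverParams
from lactoflow import qpcr, synthetic


@pytest.fixture
def base_params() -> TurnoverParams:
    """Plausible dam/litter two-pool parameters for a mid-lactation rat dyad."""
    return TurnoverParams(W_d=200.0, W_l=150.0, k_dl=0.0117, k_de=0.004, k_le=0.010)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_config() -> SimConfig:
    """Simulation with every stochastic term switched off."""
    return SimConfig(
        seed=11,
        enrichment_noise_cv=0.0,
        inter_animal_cv=0.0,
        cq_noise_sd=0.0,
        sample_effect_sd=0.0,
        hormone_noise_cv=0.0,
    )


@pytest.fixture
def noiseless_expression(noiseless_config):
    """Expression matrix from a zero-noise simulated Cq table."""
    cq = synthetic.simulate_cq(noiseless_config)
    dcq = qpcr.delta_cq(cq, synthetic.HKG["mammary"])
    return qpcr.neg_ddcq(dcq, ("CTL", "L12"), hkg_set=synthetic.HKG["mammary"])
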