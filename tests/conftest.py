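import numpy as np
import pytest

from lyorelax.mse import MSEParams
from lyorelax.simulate import SyntheticStudyConfig


@pytest.fixture
def quiet_config() -> SyntheticStudyConfig:
    """Generator configuration with every noise term switched off."""
    return SyntheticStudyConfig(
        imc_noise_sd_uW=0.0, imc_drift_uW_per_h=0.0, cryst_noise_sd_h=0.0, dsc_snr=0.0
    )


@pytest.fixture
def default_config() -> SyntheticStudyConfig:
    return SyntheticStudyConfig()


def random_valid_params(rng: np.random.Generator, beta_min: float = 0.05) -> MSEParams:
    """Admissible MSE parameter set: tau1 and the tau0-tau1 gap log-uniform,
    beta uniform over its interval."""
    tau1 = float(np.exp(rng.uniform(np.log(0.2), np.log(3.0))))
    gap = float(np.exp(rng.uniform(np.log(0.3), np.log(5.0))))
    beta = float(rng.uniform(beta_min, 1.0))
    return MSEParams(tau0=tau1 + gap, tau1=tau1, beta=beta)
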