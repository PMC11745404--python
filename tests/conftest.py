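import numpy as np
import pytest

import openstate as osx


@pytest.fixture(scope="session")
def bins():
    return osx.TemperatureBins()


@pytest.fixture(scope="session")
def logistic_truth():
    return osx.GroundTruthModel("logistic", {"r": 0.3, "K": 60.0},
                                process_noise=2.0, obs_noise=0.0)


@pytest.fixture(scope="session")
def small_logistic_panel(logistic_truth):
    """Fast panel for unit tests: 800 logistic plots in one bin."""
    cfg = osx.SyntheticConfig(n_plots=800, years=21, seed=123,
                              mat_range=(-2.0, -1.6))
    return osx.generate_panel(logistic_truth, cfg)


@pytest.fixture(scope="session")
def pure_noise_panel():
    """Driftless diffusion panel (f=0, g=1, h=0) for noise-separation tests."""
    truth = osx.GroundTruthModel(
        "custom", custom_drift=lambda x: np.zeros_like(x),
        process_noise=1.0, obs_noise=0.0)
    cfg = osx.SyntheticConfig(n_plots=5000, years=21, seed=31)
    return osx.generate_panel(truth, cfg)
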