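import numpy as np
import pytest

from vegattrib.synth import CO2History, SceneConfig, make_scene


@pytest.fixture(scope="session")
def co2_history():
    return CO2History()


@pytest.fixture(scope="session")
def small_scene():
    """A 4x4 scene with every forcing active, shared across tests."""
    cfg = SceneConfig(n_lat=4, n_lon=4, seed=42, precip_trend=0.25,
                      temp_trend=0.02, temp_noise_sd=1.0, lu_trend=-0.001,
                      vcr_intercept=0.80, vcr_slope_t=-0.03, noise_sd=0.01)
    return make_scene(cfg)


@pytest.fixture(scope="session")
def recovery_result():
    """The full-pipeline recovery experiment (computed once per session)."""
    from vegattrib.experiments import recovery_experiment
    return recovery_experiment(seed=1)
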