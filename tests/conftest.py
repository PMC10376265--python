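import numpy as np
import pytest

import rogredox as rx


@pytest.fixture(scope="session")
def calib() -> rx.CalibrationState:
    """Default instrument truth: R_red=0.2, R_ox=2.0, k=0.5."""
    return rx.CalibrationState.from_ratios(0.2, 2.0, 0.5)


@pytest.fixture(scope="session")
def constants() -> rx.NernstConstants:
    return rx.NernstConstants()


@pytest.fixture
def quiet_config() -> rx.ScenarioConfig:
    """Noise-free control scenario for exactness/oracle tests."""
    return rx.scenario("control", seed=7, noise=rx.NoiseParams.zero())


@pytest.fixture
def small_config() -> rx.ScenarioConfig:
    """Default-noise control scenario, small images for speed."""
    return rx.scenario("control", seed=7, image_shape=(128, 128), n_cells=6)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
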