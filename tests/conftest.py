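import numpy as np
import pytest

from clonesim import ModelParams


@pytest.fixture
def params5() -> ModelParams:
    """Baseline parameters with the driver cap used for prevention
    figures (N = 5)."""
    return ModelParams(max_extra_drivers=5)


@pytest.fixture
def params9() -> ModelParams:
    """Baseline parameters with the driver cap used for post-diagnostic
    protocols (N = 9)."""
    return ModelParams(max_extra_drivers=9)


@pytest.fixture
def params_single() -> ModelParams:
    """Single-type process: no extra drivers, no mutation."""
    return ModelParams(max_extra_drivers=0, driver_mut_rate=0.0, resistance_mut_rate=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
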