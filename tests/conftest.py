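import numpy as np
import pytest

from nanokymo.simulate import ChannelGeometry, NoiseParams


@pytest.fixture
def small_geometry() -> ChannelGeometry:
    return ChannelGeometry(width_nm=63.0, depth_nm=30.0, n_pixels=128)


@pytest.fixture
def quiet_noise() -> NoiseParams:
    """Deterministic envelope only: every stochastic amplitude zeroed."""
    return NoiseParams(amp_A=0.0, d_x=0.0, n_theta=0.0, dirt_amp=0.0,
                       x0_bg=1500.0, lambda_bg=800.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
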