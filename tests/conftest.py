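import numpy as np
import pytest

from sipmsim import SiPMDeviceParams


@pytest.fixture
def small_device():
    """Modest array with a 20 ns recharge, convenient for closed-form checks."""
    return SiPMDeviceParams(
        n_microcells=100,
        recharge_time_constant_s=20e-9,
        pde=1.0,
        single_cell_gain=1.0,
    )


@pytest.fixture
def one_cell_device():
    return SiPMDeviceParams(
        n_microcells=1,
        recharge_time_constant_s=20e-9,
        pde=1.0,
        single_cell_gain=2.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
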