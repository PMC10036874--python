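import numpy as np
import pytest

from imagcond import design, synth
from imagcond.design import Phase


@pytest.fixture(scope="session")
def imagery_acquisition():
    return design.build_acquisition_schedule(Phase.IMAGERY_ACQUISITION, "p01", 1)


@pytest.fixture(scope="session")
def visual_acquisition():
    return design.build_acquisition_schedule(Phase.VISUAL_ACQUISITION, "p01", 1)


@pytest.fixture(scope="session")
def habituation():
    return design.build_habituation_schedule(Phase.IMAGERY_ACQUISITION, "p01", 7)


@pytest.fixture()
def quiet_scr_config():
    """Noise-free SCR generation: every trial responds with a 0.5 µS event."""
    return synth.SynthConfig(
        scr_amp_csplus=0.5,
        scr_amp_csminus=0.5,
        scr_amp_us=0.0,
        scr_zero_prob=0.0,
        scr_noise_sd=0.0,
        scr_drift=0.0,
        participant_amp_sd=0.0,
    )


class FlatTrace:
    """Analytic stand-in trace: constant conductance."""

    def __init__(self, level: float, duration: float = 20.0, fs: float = 100.0):
        self.sampling_rate = fs
        self.values = np.full(int(duration * fs) + 1, float(level))
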