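import numpy as np
import pytest

from bhcvr import make_paradigm
from bhcvr.physio import detect_end_tidal_peaks, interpolate_and_detrend
from bhcvr.simulate import simulate_capnograph


@pytest.fixture(scope="session")
def ist_paradigm():
    """Default four-trial end-expiration layout (269 s, 15 s holds)."""
    return make_paradigm()


@pytest.fixture(scope="session")
def noiseless_capno(ist_paradigm):
    return simulate_capnograph(ist_paradigm, noise_sd=0.0)


@pytest.fixture(scope="session")
def petco2_trace(noiseless_capno):
    peaks = detect_end_tidal_peaks(noiseless_capno.trace)
    return interpolate_and_detrend(peaks)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
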