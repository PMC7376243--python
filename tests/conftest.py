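import numpy as np
import pytest

from vocptb.gcims import IMSSpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrum(intensities, sample_id="S", retention=None, drift=None) -> IMSSpectrum:
    """Spectrum with unit-spaced axes unless given explicitly."""
    m = np.asarray(intensities, dtype=float)
    if retention is None:
        retention = np.arange(m.shape[0], dtype=float)
    if drift is None:
        drift = np.arange(m.shape[1], dtype=float)
    return IMSSpectrum(sample_id, retention, drift, m)


@pytest.fixture
def spectrum_factory():
    return make_spectrum
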