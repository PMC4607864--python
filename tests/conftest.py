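import numpy as np
import pytest

from voxmon.signal_io import CalibrationMap, RawSignal
from voxmon.synth import VoiceSpec, synth_glottal_flow

FS = 11025.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def identity_cal():
    """Calibration mapping the synthetic full-scale level range into typical
    speech SPL (a unit-amplitude frame sits near 95 dB SPL)."""
    return CalibrationMap(slope=1.0, intercept=95.0, r=1.0)


@pytest.fixture(scope="session")
def pulse_train():
    """1 s of clean 200-Hz triangular glottal pulses (OQ 0.6, SQ 200) plus
    the generator's closed-form cycle table."""
    spec = VoiceSpec(f0_hz=200.0, duration_s=1.0, open_fraction=0.6,
                     speed_ratio=2.0)
    return synth_glottal_flow(spec, FS)


def sine(freq, duration_s=1.0, amp=0.3, fs=FS):
    t = np.arange(int(round(duration_s * fs))) / fs
    return RawSignal(amp * np.sin(2 * np.pi * freq * t), fs)
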