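import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "default", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

FS = 250.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine():
    def make(freq, duration_s=120.0, fs=FS, amp=1.0, phase=0.0):
        t = np.arange(int(round(duration_s * fs))) / fs
        return amp * np.sin(2 * np.pi * freq * t + phase)
    return make


@pytest.fixture
def short_recording(rng):
    """A 130-s 4-channel noise recording (one full epoch plus remainder)."""
    from fpcoma import Recording, CHANNELS
    data = rng.standard_normal((4, int(FS * 130))) * 20.0
    return Recording(CHANNELS, data, FS, "subj01")
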