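import numpy as np
import pytest

from osaconnect.io import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240306)


@pytest.fixture
def four_channel_recording(rng):
    """A short 4-channel 200 Hz recording of mixed sinusoids + noise."""
    fs = 200.0
    t = np.arange(int(fs * 40)) / fs
    data = np.stack(
        [
            10 * np.sin(2 * np.pi * 2.0 * t + p) + rng.standard_normal(t.size)
            for p in (0.0, 0.4, 0.9, 1.4)
        ]
    )
    return Recording(
        channel_labels=["F4-A1", "F3-A2", "O1-A2", "O2-A1"],
        fs=fs,
        data=data,
        subject_id="fix01",
        group_label="UNKNOWN",
    )
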