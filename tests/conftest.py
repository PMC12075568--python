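import numpy as np
import pandas as pd
import pytest

from neurovibe.pipeline_io import BehavioralTable, VoiceRecording


@pytest.fixture
def toy_table():
    """4 subjects x 3 features, one missing cell, binary labels."""
    data = pd.DataFrame({
        "a": [1.0, 1.0, 5.0, 9.0],
        "b": [2.0, np.nan, 6.0, 10.0],
        "c": [3.0, 3.0, 7.0, 11.0],
    })
    return BehavioralTable(data, pd.Series([0, 0, 1, 1]))


@pytest.fixture
def pulse_train():
    """Ideal impulse train, period 160 samples at 16 kHz (f0 = 100 Hz)."""
    x = np.zeros(16000)
    x[::160] = 1.0
    return VoiceRecording(x, 16000)


def make_recording(x, rate=16000, label=0):
    return VoiceRecording(np.asarray(x, dtype=float), rate, label=label)
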