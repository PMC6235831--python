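import numpy as np
import pytest

from synaptrain import Recording, StimulusProtocol


@pytest.fixture
def train_protocol():
    return StimulusProtocol(frequency_hz=20.0, n_stimuli=3, label="train20")


@pytest.fixture
def simple_recording(train_protocol):
    sweeps = np.array([[10.0, 20.0, 30.0], [12.0, 22.0, 32.0]])
    return Recording(sweeps, train_protocol, condition_label="WT", noise_sd_pA=2.0)


def make_recording(sweeps, frequency_hz=20.0, noise_sd_pA=0.0, label=""):
    arr = np.atleast_2d(np.asarray(sweeps, dtype=float))
    proto = StimulusProtocol(frequency_hz=frequency_hz, n_stimuli=arr.shape[1])
    return Recording(arr, proto, condition_label=label, noise_sd_pA=noise_sd_pA)
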