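import numpy as np
import pytest

from hdieeg.io import EEGRecording, MONTAGE_8
from hdieeg.synthetic import SubjectSpec, simulate_recording

FS = 125.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """Noise- and blink-free recording: a pure 10 Hz alpha tone everywhere."""
    t = np.arange(int(10 * FS)) / FS
    data = np.tile(np.sin(2 * np.pi * 10 * t)[:, None], (1, len(MONTAGE_8)))
    return EEGRecording(data, MONTAGE_8, FS, subject_id="tone")


@pytest.fixture
def quiet_recording():
    """Realistic but artifact-free synthetic EEG (no blinks, mild noise)."""
    spec = SubjectSpec(seed=42, blink_rate_hz=0.0, noise_amp=1.5)
    return simulate_recording(spec, duration_s=30.0, fs=FS, subject_id="quiet")


@pytest.fixture
def blinky_recording():
    """Synthetic EEG with ground-truth blink events."""
    spec = SubjectSpec(seed=7, blink_rate_hz=0.25)
    rec, truth = simulate_recording(spec, duration_s=60.0, fs=FS,
                                    subject_id="blinky", return_truth=True)
    return rec, truth
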