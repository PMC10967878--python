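import numpy as np
import pytest
from scipy import signal

from hdieeg.io import EEGRecording, MONTAGE_8
from hdieeg.preprocess import (
    BlinkEvents,
    FilterSpec,
    bandpass,
    correct_blinks,
    detect_blinks,
    notch,
)
from hdieeg.synthetic import SubjectSpec, simulate_recording

FS = 125.0


def _sine_rec(freq, n=int(20 * FS), amp=1.0):
    t = np.arange(n) / FS
    x = amp * np.sin(2 * np.pi * freq * t)
    return EEGRecording(np.tile(x[:, None], (1, 8)), MONTAGE_8, FS)


def _trimmed_rms(x, trim=int(2 * FS)):
    return np.sqrt(np.mean(x[trim:-trim] ** 2))


class TestBandpass:
    def test_stopband_sine_suppressed(self):
        rec = _sine_rec(1.0)
        out = bandpass(rec)
        assert _trimmed_rms(out.data[:, 0]) < 0.05 * _trimmed_rms(rec.data[:, 0])

    def test_passband_sine_preserved(self):
        rec = _sine_rec(10.0)
        out = bandpass(rec)
        amp = np.abs(out.data[int(2 * FS) : -int(2 * FS), 0]).max()
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_zero_signal_maps_to_zero(self):
        rec = EEGRecording(np.zeros((500, 8)), MONTAGE_8, FS)
        assert np.allclose(bandpass(rec).data, 0)

    def test_cutoff_above_nyquist_rejected(self):
        rec = _sine_rec(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, FilterSpec(high_hz=70.0))

    def test_linearity(self, rng):
        x = EEGRecording(rng.normal(size=(1000, 8)), MONTAGE_8, FS)
        y = EEGRecording(rng.normal(size=(1000, 8)), MONTAGE_8, FS)
        combo = EEGRecording(2.0 * x.data + 3.0 * y.data, MONTAGE_8, FS)
        lhs = bandpass(combo).data
        rhs = 2.0 * bandpass(x).data + 3.0 * bandpass(y).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_zero_phase_no_group_delay(self):
        rec = _sine_rec(10.0)
        out = bandpass(rec)
        trim = int(2 * FS)
        a = rec.data[trim:-trim, 0]
        b = out.data[trim:-trim, 0]
        xc = np.correlate(a, b, mode="full")
        lag = np.argmax(xc) - (len(a) - 1)
        assert lag == 0


class TestNotch:
    def test_line_frequency_suppressed(self):
        rec = _sine_rec(50.0)
        out = notch(rec)
        assert _trimmed_rms(out.data[:, 0]) < 0.1 * _trimmed_rms(rec.data[:, 0])

    def test_far_frequency_preserved(self):
        rec = _sine_rec(10.0)
        out = notch(rec)
        amp = np.abs(out.data[int(2 * FS) : -int(2 * FS), 0]).max()
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_magnitude_minimum_at_center(self):
        spec = FilterSpec(kind="notch")
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=FS)
        freqs = np.linspace(1, 62, 2000)
        _, h = signal.freqz(b, a, worN=freqs, fs=FS)
        assert freqs[np.argmin(np.abs(h))] == pytest.approx(50.0, abs=0.1)

    def test_notch_above_nyquist_rejected(self):
        rec = _sine_rec(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            notch(rec, FilterSpec(kind="notch", notch_hz=80.0))


class TestDetectBlinks:
    def test_injected_blinks_found(self, blinky_recording):
        rec, truth = blinky_recording
        events = detect_blinks(rec)
        true_ivs = truth["blink_intervals"]
        hits = sum(
            any(a < tb and b > ta for a, b in events.intervals)
            for ta, tb in true_ivs
        )
        assert hits / len(true_ivs) >= 0.8
        # no more than a couple of spurious detections
        assert len(events) <= len(true_ivs) + 2

    def test_blink_free_recording_gives_none(self, quiet_recording):
        assert len(detect_blinks(quiet_recording)) == 0

    def test_zero_signal_gives_none(self):
        rec = EEGRecording(np.zeros((1000, 8)), MONTAGE_8, FS)
        assert len(detect_blinks(rec)) == 0

    def test_absent_channel_rejected(self, quiet_recording):
        with pytest.raises(KeyError):
            detect_blinks(quiet_recording, channel="Cz")

    def test_deterministic(self, blinky_recording):
        rec, _ = blinky_recording
        assert detect_blinks(rec).intervals == detect_blinks(rec).intervals


class TestCorrectBlinks:
    @pytest.fixture
    def corrected_setup(self):
        """Same seed with and without blinks: ground-truth clean signal."""
        clean = simulate_recording(SubjectSpec(seed=7, blink_rate_hz=0.0), 60.0)
        dirty = simulate_recording(SubjectSpec(seed=7, blink_rate_hz=0.25), 60.0)
        events = detect_blinks(dirty)
        assert len(events) > 0
        return clean, dirty, events

    def test_blink_energy_halved_and_clean_part_untouched(self, corrected_setup):
        clean, dirty, events = corrected_setup
        out = correct_blinks(dirty, events)
        m = events.mask(dirty.n_samples)
        sos = signal.butter(4, [0.5, 4], btype="bandpass", fs=FS, output="sos")

        def delta_energy(x):
            return np.sum(signal.sosfiltfilt(sos, x, axis=0)[m] ** 2)

        assert delta_energy(out.data) < 0.5 * delta_energy(dirty.data)
        rmse_unc = np.sqrt(np.mean((dirty.data[~m] - clean.data[~m]) ** 2))
        rmse_cor = np.sqrt(np.mean((out.data[~m] - clean.data[~m]) ** 2))
        assert rmse_cor <= 1.1 * rmse_unc

    def test_closer_to_ground_truth_inside_blinks(self, corrected_setup):
        clean, dirty, events = corrected_setup
        out = correct_blinks(dirty, events)
        m = events.mask(dirty.n_samples)
        rmse_unc = np.sqrt(np.mean((dirty.data[m] - clean.data[m]) ** 2))
        rmse_cor = np.sqrt(np.mean((out.data[m] - clean.data[m]) ** 2))
        assert rmse_cor < rmse_unc

    def test_second_pass_changes_little(self, corrected_setup):
        _, dirty, events = corrected_setup
        m = events.mask(dirty.n_samples)
        sos = signal.butter(4, [0.5, 4], btype="bandpass", fs=FS, output="sos")

        def delta_energy(x):
            return np.sum(signal.sosfiltfilt(sos, x, axis=0)[m] ** 2)

        once = correct_blinks(dirty, events)
        twice = correct_blinks(once, events)
        extra = abs(delta_energy(once.data) - delta_energy(twice.data))
        assert extra < 0.1 * delta_energy(dirty.data)

    def test_empty_events_identity(self, quiet_recording):
        out = correct_blinks(quiet_recording, BlinkEvents([]))
        np.testing.assert_array_equal(out.data, quiet_recording.data)

    def test_all_blink_recording_rejected(self, quiet_recording):
        n = quiet_recording.n_samples
        with pytest.raises(ValueError, match="clean"):
            correct_blinks(quiet_recording, BlinkEvents([(0, n)]))
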