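"""Ground-truth EEG simulation for validating the processing chain.

Generates the statistical structure the method assumes: band-limited
oscillations around an individual alpha peak (posterior-dominant alpha,
frontal theta and beta), 1/f background noise, frontally-weighted eye-blink
transients, and injectable amplitude/drift/jump artifacts. Cohorts add
per-subject variability and per-condition band-amplitude multipliers that
encode the workload/attention signature of distraction (more frontal theta,
less frontal beta in distracted conditions).

Everything is a pure function of its seed: identical seeds give identical
recordings, cohorts, and ground-truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .io import EEGRecording, MONTAGE_8, FRONTAL, PARIETAL

__all__ = [
    "SubjectSpec",
    "CohortSpec",
    "DEFAULT_CONDITIONS",
    "simulate_recording",
    "simulate_cohort",
    "inject_artifacts",
    "correlated_covariate",
]

#: Default per-(band, region) oscillation amplitudes, uV (sinusoid-equivalent:
#: an entry A contributes ~A^2/2 uV^2 of band power on each region channel).
DEFAULT_BAND_AMPS: dict[tuple[str, str], float] = {
    ("theta", "frontal"): 4.0,
    ("theta", "parietal"): 1.5,
    ("alpha", "frontal"): 2.0,
    ("alpha", "parietal"): 6.0,
    ("beta", "frontal"): 3.0,
    ("beta", "parietal"): 1.0,
}

#: Condition multipliers on band amplitudes, emulating a graded secondary-task
#: load: distraction raises frontal theta and suppresses frontal beta.
DEFAULT_CONDITIONS: dict[str, dict[str, float]] = {
    "Focused": {},
    "ACPT": {"theta": 1.1, "beta": 0.95},
    "Matrix": {"theta": 1.25, "beta": 0.9},
    "SURT": {"theta": 1.4, "beta": 0.8},
}

_REGIONS = {"frontal": FRONTAL.channels, "parietal": PARIETAL.channels}


@dataclass
class SubjectSpec:
    """Generator parameters for one simulated subject.

    ``band_amps`` maps (band, region) to an oscillation amplitude in uV;
    ``osc_mode`` is ``"narrowband"`` (band-limited noise carrier, +/-1 Hz
    around the band's center frequency — spectra resemble EEG) or ``"tone"``
    (pure sinusoid, for closed-form tests). ``noise_exponent`` is the 1/f
    slope of the background, ``noise_amp`` its RMS in uV. Blink transients
    are 400 ms raised cosines at ``blink_amp`` on the AF channels (10% on
    parietal sites), arriving at ``blink_rate_hz``.
    """

    iaf_hz: float = 10.0
    band_amps: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPS)
    )
    osc_mode: str = "narrowband"
    noise_exponent: float = 1.0
    noise_amp: float = 3.0
    blink_rate_hz: float = 0.2
    blink_amp: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 8.0 < self.iaf_hz < 13.0:
            raise ValueError(f"iaf_hz must lie in (8, 13), got {self.iaf_hz}")
        if any(a < 0 for a in self.band_amps.values()):
            raise ValueError("band amplitudes must be non-negative")

    def band_center(self, band: str) -> float:
        """Oscillation carrier frequency: band centers anchored to the IAF
        (theta IAF-6, alpha at the IAF itself, beta IAF+11)."""
        return {"theta": self.iaf_hz - 6, "alpha": self.iaf_hz,
                "beta": self.iaf_hz + 11}[band]


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    cur = x.std()
    return x * (rms / cur) if cur > 0 else x


def _oscillation(rng: np.random.Generator, n: int, fs: float,
                 center: float, amp: float, mode: str) -> np.ndarray:
    """Sinusoid-equivalent amplitude calibration: output band power ~ amp^2/2."""
    if amp == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    if mode == "tone":
        return amp * np.sin(2 * np.pi * center * t + rng.uniform(0, 2 * np.pi))
    lo, hi = max(center - 1.0, 0.1), center + 1.0
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad so filter transients do not bias the short-recording RMS
    pad = int(2 * fs)
    carrier = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    cur = carrier.std()
    return carrier * (amp / np.sqrt(2) / cur) if cur > 0 else carrier


def _blink_template(fs: float, width_s: float = 0.4) -> np.ndarray:
    m = int(round(width_s * fs))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / m))


def simulate_recording(
    spec: SubjectSpec,
    duration_s: float = 60.0,
    fs: float = 125.0,
    subject_id: str = "S00",
    condition: str = "Focused",
    scenario: str = "",
    band_multipliers: dict[str, float] | None = None,
    return_truth: bool = False,
):
    """Simulate one 8-channel recording.

    Channels within a region share each band's oscillatory source (regional
    synchrony is what GFP summarizes); 1/f noise is independent per channel;
    blinks hit the AF channels at full amplitude and parietal sites at 10%.
    With ``return_truth=True`` also returns a dict with the blink intervals
    (half-open sample spans) and the effective band amplitudes.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(spec.seed)
    mult = band_multipliers or {}
    data = np.zeros((n, len(MONTAGE_8)))
    col = {c: i for i, c in enumerate(MONTAGE_8)}

    eff_amps: dict[tuple[str, str], float] = {}
    for (band, region), amp in spec.band_amps.items():
        amp_eff = amp * mult.get(band, 1.0)
        eff_amps[(band, region)] = amp_eff
        wave = _oscillation(rng, n, fs, spec.band_center(band), amp_eff,
                            spec.osc_mode)
        for ch in _REGIONS[region]:
            data[:, col[ch]] += wave

    if spec.noise_amp > 0:
        for i in range(len(MONTAGE_8)):
            data[:, i] += _pink_noise(rng, n, fs, spec.noise_exponent,
                                      spec.noise_amp)

    blink_intervals: list[tuple[int, int]] = []
    if spec.blink_rate_hz > 0 and spec.blink_amp > 0:
        tmpl = _blink_template(fs)
        m = len(tmpl)
        n_blinks = rng.poisson(spec.blink_rate_hz * duration_s)
        starts = np.sort(rng.integers(0, max(1, n - m), size=n_blinks))
        last_end = -m
        for s in starts:
            if s < last_end + m:  # keep blinks non-overlapping
                continue
            for ch in MONTAGE_8:
                gain = 1.0 if ch.upper().startswith("AF") else 0.1
                data[s : s + m, col[ch]] += spec.blink_amp * gain * tmpl
            blink_intervals.append((int(s), int(s + m)))
            last_end = s

    rec = EEGRecording(
        data=data, channel_labels=MONTAGE_8, fs=fs,
        subject_id=subject_id, condition=condition, scenario=scenario,
    )
    if return_truth:
        return rec, {"blink_intervals": blink_intervals, "band_amps": eff_amps}
    return rec


@dataclass
class CohortSpec:
    """A repeated-measures cohort: every subject is recorded once per
    condition (plus a per-scenario focused baseline run for z-scoring).

    ``conditions`` maps condition label to band-amplitude multipliers;
    ``iaf_range`` bounds the per-subject alpha peak draw; ``amp_jitter_sd``
    is the SD of the lognormal per-subject amplitude jitter.
    """

    n_subjects: int = 25
    conditions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONDITIONS.items()}
    )
    segment_len_s: float = 60.0
    scenario: str = "City"
    iaf_range: tuple[float, float] = (8.6, 12.4)
    amp_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for cond, mult in self.conditions.items():
            if any(m <= 0 for m in mult.values()):
                raise ValueError(f"non-positive multiplier in condition {cond!r}")


def simulate_cohort(
    cohort: CohortSpec,
    base: SubjectSpec | None = None,
    seed: int = 0,
    fs: float = 125.0,
    include_baseline: bool = True,
):
    """Simulate a labeled cohort.

    Returns ``(recordings, truth)`` where ``recordings`` maps
    ``(subject_id, condition)`` to an :class:`EEGRecording` (condition
    ``"Baseline"`` is the focused-driving normalization run) and ``truth``
    is a tidy DataFrame with one row per subject x condition x band x region
    recording the drawn IAF, amplitude and multiplier.
    """
    base = base or SubjectSpec()
    master = np.random.SeedSequence(seed)
    subj_seqs = master.spawn(cohort.n_subjects)
    recordings: dict[tuple[str, str], EEGRecording] = {}
    rows = []
    for si, seq in enumerate(subj_seqs):
        sid = f"S{si + 1:03d}"
        rng = np.random.default_rng(seq)
        lo, hi = cohort.iaf_range
        iaf = float(rng.uniform(lo, hi))
        amps = {
            k: a * float(np.exp(rng.normal(0, cohort.amp_jitter_sd)))
            for k, a in base.band_amps.items()
        }
        conds = dict(cohort.conditions)
        if include_baseline:
            conds = {"Baseline": {}, **conds}
        for cond, mult in conds.items():
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(base, iaf_hz=iaf, band_amps=amps, seed=sub_seed)
            recordings[(sid, cond)] = simulate_recording(
                spec, duration_s=cohort.segment_len_s, fs=fs,
                subject_id=sid, condition=cond, scenario=cohort.scenario,
                band_multipliers=mult,
            )
            for (band, region), amp in amps.items():
                rows.append(
                    {
                        "subject": sid, "condition": cond,
                        "scenario": cohort.scenario, "iaf_hz": iaf,
                        "band": band, "region": region,
                        "amplitude_uv": amp,
                        "multiplier": mult.get(band, 1.0),
                    }
                )
    return recordings, pd.DataFrame(rows)


_ARTIFACT_KINDS = ("amplitude", "drift", "jump")


def inject_artifacts(
    rec: EEGRecording,
    plan: list[tuple[int, str, float]],
    epoch_len_s: float = 1.0,
    channel: str = "AFz",
):
    """Corrupt chosen epochs so a known rejection criterion must fire.

    ``plan`` rows are ``(epoch_index, kind, magnitude)`` with kind one of
    ``amplitude`` (DC offset of ``magnitude`` uV on one channel), ``drift``
    (centered linear ramp of slope ``magnitude`` uV/s), or ``jump`` (a
    centered 3-sample boxcar of height ``magnitude`` uV, i.e. a step up and
    back down between consecutive samples). Each injection is confined to
    its epoch and shaped so only its own criterion exceeds the default
    bounds. Returns the corrupted recording plus a ground-truth DataFrame
    mapping epoch index to the criterion that should flag it.
    """
    elen = int(round(epoch_len_s * rec.fs))
    n_ep = rec.n_samples // elen
    seen: set[tuple[int, str]] = set()
    data = rec.data.copy()
    ci = rec.channel_indices([channel])[0]
    rows = []
    for idx, kind, mag in plan:
        if kind not in _ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        if not 0 <= idx < n_ep:
            raise IndexError(f"epoch index {idx} out of range (0..{n_ep - 1})")
        if (idx, kind) in seen:
            raise ValueError(f"duplicate injection {kind!r} on epoch {idx}")
        seen.add((idx, kind))
        a = idx * elen
        if kind == "amplitude":
            data[a : a + elen, ci] += mag
            expect = "threshold"
        elif kind == "drift":
            t = (np.arange(elen) - (elen - 1) / 2) / rec.fs
            data[a : a + elen, ci] += mag * t
            expect = "trend"
        else:
            mid = a + elen // 2
            data[mid : mid + 3, ci] += mag
            expect = "jump"
        rows.append({"epoch_index": idx, "kind": kind, "magnitude": mag,
                     "channel": channel, "expected_flag": expect})
    return rec.with_data(data), pd.DataFrame(rows)


def correlated_covariate(
    values_by_subject: dict[str, np.ndarray],
    rho: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """A behavioral covariate (e.g., horizontal-gaze SD) with a prescribed
    within-subject correlation ``rho`` to each subject's series.

    Per subject the series is standardized and mixed with independent
    Gaussian noise as ``rho * z + sqrt(1 - rho^2) * e``, so the population
    within-subject correlation is ``rho`` while between-subject offsets are
    free (each subject gets its own random baseline shift).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for sid, vals in values_by_subject.items():
        v = np.asarray(vals, dtype=float)
        sd = v.std()
        z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        e = rng.standard_normal(v.size)
        offset = rng.normal(0, 2.0)
        out[sid] = rho * z + np.sqrt(1 - rho**2) * e + offset
    return out
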