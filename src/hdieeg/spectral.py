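"""Individual alpha frequency, IAF-anchored bands, and per-epoch Global
Field Power.

The subject's Individual Alpha Frequency (IAF) is the frequency of the
highest spectral peak within the classical alpha range (8-13 Hz) during
eyes-open rest, estimated from a Welch spectrum of the posterior channels.
The three analysis bands are anchored to it:

    theta = [IAF - 8, IAF - 4) Hz
    alpha = [IAF - 2, IAF + 2) Hz
    beta  = [IAF + 2, IAF + 20) Hz

so that IAF = 10 Hz reproduces the standard 2-6 / 8-12 / 12-30 Hz
definitions. Intervals are half-open to keep the shared alpha/beta edge
unambiguous.

Global Field Power (GFP) for a band and channel region is, per 1-s epoch,
the mean over the region's N channels of the time-averaged squared
band-restricted signal, in uV^2. The band restriction is spectral: each
epoch is Hanning-tapered, Fourier-transformed (1 Hz resolution at 1-s
epochs), and power is summed over the in-band bins with window-power
normalization, which by Parseval equals the time-domain mean square of the
band-limited signal without per-epoch filter transients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EEGRecording, PARIETAL, RegionSpec
from .rejection import EpochSet

__all__ = [
    "BandScheme",
    "SpectralConfig",
    "GFPSeries",
    "estimate_iaf",
    "band_ranges",
    "compute_gfp",
]

BANDS = ("theta", "alpha", "beta")


@dataclass
class BandScheme:
    """IAF value and the three IAF-anchored band ranges, in Hz."""

    iaf_hz: float
    theta: tuple[float, float]
    alpha: tuple[float, float]
    beta: tuple[float, float]

    def band(self, name: str) -> tuple[float, float]:
        if name not in BANDS:
            raise KeyError(f"unknown band {name!r}; expected one of {BANDS}")
        return getattr(self, name)


def band_ranges(iaf: float) -> BandScheme:
    """IAF-anchored band ranges; requires IAF > 8 Hz so theta stays above DC."""
    if not iaf > 8:
        raise ValueError(
            f"IAF must exceed 8 Hz (got {iaf}): the theta band lower edge "
            "IAF - 8 would reach DC"
        )
    return BandScheme(
        iaf_hz=iaf,
        theta=(iaf - 8, iaf - 4),
        alpha=(iaf - 2, iaf + 2),
        beta=(iaf + 2, iaf + 20),
    )


@dataclass
class SpectralConfig:
    """Windowing and search parameters for the spectral estimators.

    ``window_len_s`` matches the epoch length (1 s -> 1 Hz resolution);
    ``alpha_search`` is the classical alpha range scanned for the IAF peak;
    ``peak_prominence_ratio`` is how far above the within-range median power
    a candidate peak must rise to count as a real alpha peak rather than a
    noise fluctuation.
    """

    window: str = "hann"
    window_len_s: float = 1.0
    alpha_search: tuple[float, float] = (8.0, 13.0)
    iaf_channels: tuple[str, ...] = PARIETAL.channels
    peak_prominence_ratio: float = 1.25


def estimate_iaf(rest: EEGRecording, cfg: SpectralConfig | None = None) -> float:
    """Individual alpha frequency from an eyes-open rest recording.

    Welch spectrum (Hanning window of ``window_len_s``, 50% overlap)
    averaged over ``iaf_channels``; the returned value is the frequency of
    the largest strict local maximum within ``alpha_search``, refined by
    parabolic interpolation of log-power across the three bins around it.

    Raises ``ValueError("no alpha peak")`` when no local maximum rises
    ``peak_prominence_ratio`` times above the within-range median power —
    a structureless (e.g., white-noise) spectrum must not yield a silent
    default IAF.
    """
    cfg = cfg or SpectralConfig()
    nper = int(round(cfg.window_len_s * rest.fs))
    x = rest.pick(cfg.iaf_channels)
    freqs, psd = signal.welch(
        x, fs=rest.fs, window=cfg.window, nperseg=nper,
        noverlap=nper // 2, axis=0,
    )
    spectrum = psd.mean(axis=1)

    lo, hi = cfg.alpha_search
    inside = (freqs >= lo) & (freqs <= hi)
    med = np.median(spectrum[inside])
    # strict local maxima, evaluated on the full grid so range edges never win
    idx = np.flatnonzero(inside)
    peaks = [
        k for k in idx
        if 0 < k < len(freqs) - 1
        and spectrum[k] > spectrum[k - 1]
        and spectrum[k] > spectrum[k + 1]
    ]
    peaks = [k for k in peaks if spectrum[k] > cfg.peak_prominence_ratio * med]
    if not peaks:
        raise ValueError(
            "no alpha peak: no local spectral maximum rises above the "
            f"{cfg.alpha_search} Hz background"
        )
    k = max(peaks, key=lambda j: spectrum[j])
    # parabolic refinement on log power
    y0, y1, y2 = np.log(spectrum[k - 1 : k + 2])
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    df = freqs[1] - freqs[0]
    return float(freqs[k] + delta * df)


@dataclass
class GFPSeries:
    """Per-kept-epoch Global Field Power for one (band, region) pair, uV^2."""

    band: str
    region: str
    values: np.ndarray
    epoch_index: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.epoch_index = np.asarray(self.epoch_index, dtype=int)
        if self.values.shape != self.epoch_index.shape:
            raise ValueError("values and epoch_index must align")
        if np.any(self.values < 0):
            raise ValueError("GFP values must be non-negative")


def _band_power_epoch(e: np.ndarray, fs: float, low: float, high: float,
                      window: np.ndarray) -> np.ndarray:
    """Per-channel mean-square amplitude (uV^2) of one epoch restricted to
    [low, high) Hz, via windowed FFT with window-power normalization."""
    n = e.shape[0]
    xw = e * window[:, None]
    spec = np.fft.rfft(xw, axis=0)
    power = np.abs(spec) ** 2
    # one-sided correction: double everything except DC (and Nyquist if present)
    coef = np.full(power.shape[0], 2.0)
    coef[0] = 1.0
    if n % 2 == 0:
        coef[-1] = 1.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= low) & (freqs < high)
    wpow = n * np.sum(window**2)
    return (coef[in_band, None] * power[in_band]).sum(axis=0) / wpow


def compute_gfp(
    eps: EpochSet,
    scheme: BandScheme,
    band: str,
    region: RegionSpec,
    cfg: SpectralConfig | None = None,
) -> GFPSeries:
    """Global Field Power per kept epoch for one band and channel region.

    Each region channel is band-restricted spectrally within the epoch,
    its mean-square amplitude taken, and the result averaged over the
    region's N channels.
    """
    cfg = cfg or SpectralConfig()
    low, high = scheme.band(band)
    if not 0 < low < high < eps.fs / 2:
        raise ValueError(
            f"band [{low}, {high}) Hz must lie within (0, {eps.fs / 2}) Hz"
        )
    kept = eps.kept_index
    if len(kept) == 0:
        raise ValueError("no kept epochs to compute GFP on")
    lookup = {c.strip().lower(): i for i, c in enumerate(eps.channel_labels)}
    missing = [c for c in region.channels if c.strip().lower() not in lookup]
    if missing:
        raise KeyError(f"region channels not in epochs: {missing}")
    cols = [lookup[c.strip().lower()] for c in region.channels]
    window = signal.get_window(cfg.window, eps.epochs.shape[1])
    values = np.empty(len(kept))
    for j, i in enumerate(kept):
        per_chan = _band_power_epoch(
            eps.epochs[i][:, cols], eps.fs, low, high, window
        )
        values[j] = per_chan.mean()
    return GFPSeries(band=band, region=region.name, values=values, epoch_index=kept)
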