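"""Epoch segmentation and automatic artifact rejection.

The cleaned recording is cut into consecutive non-overlapping 1-s epochs and
each epoch is screened by three criteria, any of which marks it artifactual:

* threshold — any sample on any channel exceeds +/-80 uV in absolute value;
* trend — the least-squares linear slope of any channel exceeds 20 uV/s in
  absolute value (slow drifts, electrode movement);
* jump — any sample-to-sample difference on any channel exceeds 25 uV in
  absolute value (abrupt, non-physiological variation).

Equality with a threshold is not flagged (strict "exceeds"). Flagged epochs
are removed; downstream band-power statistics use kept epochs only, leaving
gaps in the epoch index rather than interpolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EEGRecording

__all__ = [
    "ArtifactCriteria",
    "EpochSet",
    "epoch",
    "flag_threshold",
    "flag_trend",
    "flag_jump",
    "reject",
    "write_rejection_log",
]

REASONS = ("threshold", "trend", "jump")


@dataclass
class ArtifactCriteria:
    """Rejection thresholds; all strict, all in microvolt units."""

    amplitude_uv: float = 80.0
    slope_uv_per_s: float = 20.0
    jump_uv: float = 25.0
    epoch_len_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("amplitude_uv", "slope_uv_per_s", "jump_uv", "epoch_len_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochSet:
    """Fixed-length epochs with per-epoch artifact flags.

    ``flags[i]`` is the set of criteria epoch ``i`` violates (empty until
    :func:`reject` runs); ``kept_index`` lists indices with no flags, in
    order. ``log`` holds one (index, reasons, worst_channel, worst_value)
    entry per flagged epoch.
    """

    epochs: np.ndarray  # (n_epochs, epoch_samples, n_channels)
    starts: np.ndarray  # start sample of each epoch
    fs: float
    channel_labels: tuple[str, ...]
    flags: list[set[str]] = field(default_factory=list)
    log: list[tuple[int, str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.flags:
            self.flags = [set() for _ in range(self.n_epochs)]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def kept_index(self) -> np.ndarray:
        return np.array(
            [i for i, f in enumerate(self.flags) if not f], dtype=int
        )

    def kept(self) -> np.ndarray:
        """Data of unflagged epochs, shape (n_kept, epoch_samples, n_channels)."""
        return self.epochs[self.kept_index]


def epoch(rec: EEGRecording, criteria: ArtifactCriteria | None = None) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    A trailing partial epoch is discarded; a recording shorter than one
    epoch is an error.
    """
    criteria = criteria or ArtifactCriteria()
    elen = int(round(criteria.epoch_len_s * rec.fs))
    n_ep = rec.n_samples // elen
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{criteria.epoch_len_s} s epoch"
        )
    trimmed = rec.data[: n_ep * elen]
    eps = trimmed.reshape(n_ep, elen, rec.n_channels)
    starts = np.arange(n_ep) * elen
    return EpochSet(eps, starts, rec.fs, rec.channel_labels)


def _worst(values: np.ndarray, labels: tuple[str, ...]) -> tuple[str, float]:
    i = int(np.argmax(np.abs(values)))
    return labels[i], float(values[i])


def flag_threshold(e: np.ndarray, criteria: ArtifactCriteria) -> bool:
    """True iff any |sample| on any channel strictly exceeds the amplitude bound."""
    return bool(np.max(np.abs(e)) > criteria.amplitude_uv)


def flag_trend(e: np.ndarray, criteria: ArtifactCriteria, fs: float) -> bool:
    """True iff any channel's least-squares slope strictly exceeds the bound.

    The slope is the OLS linear-trend coefficient of amplitude against time
    in seconds, computed per channel.
    """
    return bool(np.max(np.abs(_slopes(e, fs))) > criteria.slope_uv_per_s)


def _slopes(e: np.ndarray, fs: float) -> np.ndarray:
    t = np.arange(e.shape[0]) / fs
    t = t - t.mean()
    return (t @ (e - e.mean(axis=0))) / (t @ t)


def flag_jump(e: np.ndarray, criteria: ArtifactCriteria) -> bool:
    """True iff any sample-to-sample difference strictly exceeds the jump bound."""
    if e.shape[0] < 2:
        return False
    return bool(np.max(np.abs(np.diff(e, axis=0))) > criteria.jump_uv)


def reject(
    eps: EpochSet, criteria: ArtifactCriteria | None = None
) -> EpochSet:
    """Populate artifact flags on every epoch and drop flagged ones from
    ``kept_index``; a per-epoch log entry records the reasons and the worst
    offending channel. All epochs flagged is an error (downstream regional
    band power would be undefined)."""
    criteria = criteria or ArtifactCriteria()
    labels = eps.channel_labels
    flags: list[set[str]] = []
    log: list[tuple[int, str, str, float]] = []
    for i in range(eps.n_epochs):
        e = eps.epochs[i]
        reasons: set[str] = set()
        worst_ch, worst_val = "", 0.0
        if flag_threshold(e, criteria):
            reasons.add("threshold")
            peaks = e[np.abs(e).argmax(axis=0), np.arange(e.shape[1])]
            worst_ch, worst_val = _worst(peaks, labels)
        if flag_trend(e, criteria, eps.fs):
            reasons.add("trend")
            if not worst_ch:
                worst_ch, worst_val = _worst(_slopes(e, eps.fs), labels)
        if flag_jump(e, criteria):
            reasons.add("jump")
            if not worst_ch:
                worst_ch, worst_val = _worst(
                    np.max(np.abs(np.diff(e, axis=0)), axis=0), labels
                )
        flags.append(reasons)
        if reasons:
            log.append((i, "+".join(sorted(reasons)), worst_ch, worst_val))
    out = EpochSet(eps.epochs, eps.starts, eps.fs, labels, flags, log)
    if len(out.kept_index) == 0:
        raise ValueError("no clean epochs: every epoch was flagged as artifact")
    return out


def write_rejection_log(eps: EpochSet, path: str | Path) -> None:
    """Tab-separated rejection log: epoch index, start time, reasons,
    worst channel, worst value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch_index\tstart_time_s\treasons\tworst_channel\tworst_value\n")
        for i, reasons, ch, val in eps.log:
            t0 = eps.starts[i] / eps.fs
            fh.write(f"{i}\t{t0:.3f}\t{reasons}\t{ch}\t{val:.3f}\n")
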