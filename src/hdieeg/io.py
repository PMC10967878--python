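"""Reading, writing and montage bookkeeping for multichannel EEG recordings.

The in-memory container is :class:`EEGRecording`: a samples x channels matrix
of microvolt values plus channel labels, sampling rate and free-string
condition/scenario metadata. Two on-disk dialects are supported:

* ``fixture_table`` — a UTF-8, comma-delimited text file with ``#``-prefixed
  metadata lines (``# fs=125``, ``# subject=S01``, ``# condition=SURT``,
  ``# scenario=City``), a header row of channel labels, and one row per
  sample. Lossless; intended for small test fixtures and synthetic cohorts.
* ``edf`` — European Data Format, 16-bit. Reading goes through
  :func:`mne.io.read_raw_edf`; writing uses a minimal EDF writer included
  here, so values round-trip within the 16-bit quantization step.

All amplitudes are microvolts internally; EDF physical dimensions are
converted at load. Channel-label matching is case-insensitive after trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "RegionSpec",
    "FRONTAL",
    "PARIETAL",
    "MONTAGE_8",
    "read_recording",
    "write_recording",
]

#: The 8-channel frontal/parietal montage (prefrontal AF row plus midline and
#: lateral parietal sites), left-mastoid referenced at acquisition.
MONTAGE_8 = ("AFz", "AF3", "AF4", "AF7", "AF8", "Pz", "P3", "P4")


def _norm(label: str) -> str:
    return label.strip().lower()


@dataclass
class RegionSpec:
    """A named channel group; ``len(channels)`` is the N of the regional GFP."""

    name: str
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.channels)


FRONTAL = RegionSpec("frontal", ("AFz", "AF3", "AF4", "AF7", "AF8"))
PARIETAL = RegionSpec("parietal", ("Pz", "P3", "P4"))


@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in microvolts; must be finite (gaps are rejected at load).
    channel_labels : sequence of str
        Unique labels, one per column, order preserved from the source file.
    fs : float
        Sampling frequency in Hz.
    subject_id, condition, scenario : str
        Free-string metadata carried along; never interpreted numerically.
    """

    data: np.ndarray
    channel_labels: tuple[str, ...]
    fs: float
    subject_id: str = ""
    condition: str = ""
    scenario: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a samples x channels matrix")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[1]} data columns but "
                f"{len(self.channel_labels)} channel labels"
            )
        normed = [_norm(c) for c in self.channel_labels]
        if len(set(normed)) != len(normed):
            raise ValueError(f"duplicate channel labels: {self.channel_labels}")
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples (gaps?)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_indices(self, labels: Sequence[str]) -> np.ndarray:
        """Column indices for ``labels`` (case-insensitive, trimmed).

        Raises ``KeyError`` naming every absent label.
        """
        lookup = {_norm(c): i for i, c in enumerate(self.channel_labels)}
        missing = [lab for lab in labels if _norm(lab) not in lookup]
        if missing:
            raise KeyError(f"channels not in recording: {missing}")
        return np.array([lookup[_norm(lab)] for lab in labels], dtype=int)

    def pick(self, labels: Sequence[str]) -> np.ndarray:
        """Signal matrix restricted to ``labels``, in their given order."""
        return self.data[:, self.channel_indices(labels)]

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with ``data`` replaced (metadata kept)."""
        return replace(self, data=np.asarray(data, dtype=float))


# ---------------------------------------------------------------------------
# fixture_table dialect
# ---------------------------------------------------------------------------

_META_KEYS = {"fs", "subject", "condition", "scenario"}


def _read_fixture_table(path: Path) -> EEGRecording:
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip().lower()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                continue
            rows.append([float(v) for v in line.split(",")])
    if header is None:
        raise ValueError(f"{path}: no header row of channel labels")
    if "fs" not in meta:
        raise ValueError(f"{path}: missing '# fs=' metadata line")
    data = np.array(rows, dtype=float)
    if data.size == 0:
        data = data.reshape(0, len(header))
    return EEGRecording(
        data=data,
        channel_labels=tuple(header),
        fs=float(meta["fs"]),
        subject_id=meta.get("subject", ""),
        condition=meta.get("condition", ""),
        scenario=meta.get("scenario", ""),
    )


def _write_fixture_table(rec: EEGRecording, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        if rec.subject_id:
            fh.write(f"# subject={rec.subject_id}\n")
        if rec.condition:
            fh.write(f"# condition={rec.condition}\n")
        if rec.scenario:
            fh.write(f"# scenario={rec.scenario}\n")
        fh.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.6f", delimiter=",")


# ---------------------------------------------------------------------------
# EDF dialect
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF (16-bit) writer: one 1-s data record per second when the
    sample count allows it, otherwise a single record spanning the signal."""
    n, nchan = rec.data.shape
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if fs == spr and n % spr == 0 and n > 0:
        n_records, rec_dur = n // spr, 1.0
    else:
        n_records, rec_dur, spr = 1, n / fs, n

    # digitize with the header's (rounded) physical range, not the raw one,
    # so reader and writer agree on the scale exactly; round up so no sample
    # clips
    raw_max = np.maximum(np.max(np.abs(rec.data), axis=0), 1.0)
    phys_max = np.array([float(f"{pm * 1.0005:.5g}") for pm in raw_max])
    dig_max = 32767
    scale = phys_max / dig_max

    header_bytes = 256 + 256 * nchan
    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(rec.subject_id or "X", 80))
        fh.write(_edf_field(f"Startdate 01-JAN-2000 {rec.condition or 'X'}", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(header_bytes), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field(f"{rec_dur:g}", 8))
        fh.write(_edf_field(str(nchan), 4))
        for lab in rec.channel_labels:
            fh.write(_edf_field(lab, 16))
        for _ in range(nchan):
            fh.write(_edf_field("AgAgCl electrode", 80))
        for _ in range(nchan):
            fh.write(_edf_field("uV", 8))
        for pm in phys_max:
            fh.write(_edf_field(f"{-pm:.5g}", 8))
        for pm in phys_max:
            fh.write(_edf_field(f"{pm:.5g}", 8))
        for _ in range(nchan):
            fh.write(_edf_field(str(-dig_max), 8))
        for _ in range(nchan):
            fh.write(_edf_field(str(dig_max), 8))
        for _ in range(nchan):
            fh.write(_edf_field("", 80))
        for _ in range(nchan):
            fh.write(_edf_field(str(spr), 8))
        for _ in range(nchan):
            fh.write(_edf_field("", 32))
        digital = np.clip(
            np.round(rec.data / scale[None, :]), -dig_max, dig_max
        ).astype("<i2")
        for r in range(n_records):
            block = digital[r * spr : (r + 1) * spr, :]
            for ch in range(nchan):
                fh.write(block[:, ch].tobytes())


def _read_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    return EEGRecording(
        data=data_uv.T,
        channel_labels=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        subject_id=_edf_subject_id(path),
    )


def _edf_subject_id(path: Path) -> str:
    with open(path, "rb") as fh:
        fh.seek(8)
        return fh.read(80).decode("ascii", "replace").strip()


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "fixture_table")


def read_recording(
    path: str | Path,
    format: str = "fixture_table",
    require_channels: Sequence[str] | None = None,
) -> EEGRecording:
    """Read an EEG recording in microvolts.

    Parameters
    ----------
    path : path to the file.
    format : ``"edf"`` or ``"fixture_table"``.
    require_channels : optional labels that must be present; an explicit
        error naming the absent labels is raised otherwise. Defaults to no
        requirement; pass :data:`MONTAGE_8` to enforce the full montage.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    rec = _read_edf(path) if format == "edf" else _read_fixture_table(path)
    if require_channels is not None:
        rec.channel_indices(require_channels)  # raises naming missing labels
    return rec


def write_recording(rec: EEGRecording, path: str | Path, format: str = "fixture_table") -> None:
    """Write ``rec`` to ``path`` in the named dialect (see module docstring)."""
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if format == "edf":
        _write_edf(rec, path)
    else:
        _write_fixture_table(rec, path)
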