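"""Behavioral recovery of the rejection constants.

Each helper reconstructs one artifact-rejection bound purely from the
observable flag/no-flag behavior of the criterion predicate, by bisecting
constructed 1-s epochs: constant epochs for the amplitude bound, pure
linear ramps for the slope bound, and single mid-epoch steps for the
sample-to-sample bound. Useful as an end-user sanity check that a
configured pipeline enforces the thresholds it claims.
"""

from __future__ import annotations

import numpy as np

from .rejection import ArtifactCriteria, flag_jump, flag_threshold, flag_trend

__all__ = [
    "recover_amplitude_bound",
    "recover_slope_bound",
    "recover_jump_bound",
]


def _bisect(flagged_at, lo: float, hi: float, tol: float) -> float:
    if flagged_at(lo) or not flagged_at(hi):
        raise ValueError("bisection bracket does not straddle the flag boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flagged_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def recover_amplitude_bound(
    criteria: ArtifactCriteria | None = None,
    fs: float = 125.0,
    lo: float = 0.0,
    hi: float = 200.0,
    tol: float = 1e-3,
) -> float:
    """Amplitude bound (uV) from constant-amplitude epochs."""
    criteria = criteria or ArtifactCriteria()
    n = int(round(criteria.epoch_len_s * fs))

    def flagged(a: float) -> bool:
        return flag_threshold(np.full((n, 1), a), criteria)

    return _bisect(flagged, lo, hi, tol)


def recover_slope_bound(
    criteria: ArtifactCriteria | None = None,
    fs: float = 125.0,
    lo: float = 0.0,
    hi: float = 100.0,
    tol: float = 1e-3,
) -> float:
    """Slope bound (uV/s) from centered linear-ramp epochs."""
    criteria = criteria or ArtifactCriteria()
    n = int(round(criteria.epoch_len_s * fs))
    t = (np.arange(n) - (n - 1) / 2) / fs

    def flagged(s: float) -> bool:
        return flag_trend((s * t)[:, None], criteria, fs)

    return _bisect(flagged, lo, hi, tol)


def recover_jump_bound(
    criteria: ArtifactCriteria | None = None,
    fs: float = 125.0,
    lo: float = 0.0,
    hi: float = 100.0,
    tol: float = 1e-3,
) -> float:
    """Sample-to-sample bound (uV) from single mid-epoch step epochs."""
    criteria = criteria or ArtifactCriteria()
    n = int(round(criteria.epoch_len_s * fs))

    def flagged(h: float) -> bool:
        e = np.zeros((n, 1))
        e[n // 2 :, 0] = h
        return flag_jump(e, criteria)

    return _bisect(flagged, lo, hi, tol)
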