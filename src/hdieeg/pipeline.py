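"""End-to-end convenience chain: raw recording -> cleaned epochs ->
IAF-anchored band power -> per-epoch indices.

These helpers wire the stage modules together in the canonical order
(band-pass, notch, blink correction, epoching, artifact rejection, GFP,
indices) so scripts and tests can process a subject in two calls:
:func:`subject_band_scheme` on the eyes-open rest run, then
:func:`recording_to_indices` on each task run.
"""

from __future__ import annotations

import numpy as np

from .indices import BaselineStats, IndexSeries, baseline_stats, compute_indices
from .io import EEGRecording, FRONTAL, PARIETAL
from .preprocess import FilterSpec, preprocess_recording
from .rejection import ArtifactCriteria, EpochSet, epoch, reject
from .spectral import BandScheme, SpectralConfig, band_ranges, compute_gfp, estimate_iaf

__all__ = [
    "clean_epochs",
    "subject_band_scheme",
    "recording_to_indices",
    "normalized_hdi",
]


def clean_epochs(
    rec: EEGRecording,
    criteria: ArtifactCriteria | None = None,
    correct_blinks: bool = True,
) -> EpochSet:
    """Preprocess (filter + blink-correct) and return artifact-screened epochs."""
    clean, _ = preprocess_recording(rec, correct=correct_blinks)
    return reject(epoch(clean, criteria), criteria)


def subject_band_scheme(
    rest: EEGRecording,
    cfg: SpectralConfig | None = None,
    criteria: ArtifactCriteria | None = None,
) -> BandScheme:
    """IAF-anchored band scheme from an eyes-open rest recording.

    The rest run goes through the same cleaning and rejection chain; kept
    epochs are concatenated for the Welch IAF estimate.
    """
    eps = clean_epochs(rest, criteria)
    kept = eps.kept()
    concat = kept.reshape(-1, kept.shape[2])
    rest_clean = EEGRecording(
        data=concat, channel_labels=eps.channel_labels, fs=eps.fs,
        subject_id=rest.subject_id, condition=rest.condition,
        scenario=rest.scenario,
    )
    return band_ranges(estimate_iaf(rest_clean, cfg))


def recording_to_indices(
    rec: EEGRecording,
    scheme: BandScheme,
    cfg: SpectralConfig | None = None,
    criteria: ArtifactCriteria | None = None,
    correct_blinks: bool = True,
) -> IndexSeries:
    """Per-epoch workload, attention and HDI for one task recording."""
    eps = clean_epochs(rec, criteria, correct_blinks)
    theta_f = compute_gfp(eps, scheme, "theta", FRONTAL, cfg)
    alpha_p = compute_gfp(eps, scheme, "alpha", PARIETAL, cfg)
    beta_f = compute_gfp(eps, scheme, "beta", FRONTAL, cfg)
    return compute_indices(theta_f, alpha_p, beta_f)


def normalized_hdi(
    task: EEGRecording,
    baseline: EEGRecording,
    scheme: BandScheme,
    cfg: SpectralConfig | None = None,
    criteria: ArtifactCriteria | None = None,
    correct_blinks: bool = True,
) -> IndexSeries:
    """Task-run index series with HDI z-scored to the scenario baseline run."""
    base_series = recording_to_indices(baseline, scheme, cfg, criteria,
                                       correct_blinks)
    ref = baseline_stats(base_series.hdi, scenario=baseline.scenario)
    series = recording_to_indices(task, scheme, cfg, criteria, correct_blinks)
    return series.normalized(ref, scenario=task.scenario or None)
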