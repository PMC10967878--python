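"""The per-epoch neurometrics: mental workload, attention, and the Human
Distraction Index (HDI), with baseline z-normalization.

    workload  = frontal theta GFP / parietal alpha GFP
    attention = frontal beta GFP / frontal theta GFP   (inverse theta-beta ratio)
    HDI       = workload - attention

The construction encodes the psychology of distraction: a distracted driver
carries *more* workload (frontal theta up) while allocating *less* sustained
attention (inverse theta-beta ratio down), so the HDI rises. Because every
term is a ratio of band powers, the HDI is invariant to a global rescaling of
the EEG amplitude.

Per-epoch values are z-scored against the statistics of a focused-driving
baseline run from the same scenario (City baseline for City runs, Highway
for Highway) before group-level comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import GFPSeries

__all__ = [
    "IndexSeries",
    "BaselineStats",
    "workload",
    "attention",
    "hdi",
    "compute_indices",
    "normalize",
    "baseline_stats",
    "segment_summary",
]

#: Denominator guard: epochs whose denominator GFP falls below this are
#: dropped (logged) rather than producing infinities.
EPS_DENOM = 1e-12


def _ratio(num: GFPSeries, den: GFPSeries) -> tuple[np.ndarray, np.ndarray, list[int]]:
    if not np.array_equal(num.epoch_index, den.epoch_index):
        raise ValueError(
            "GFP series are misaligned: epoch indices differ "
            f"({len(num.epoch_index)} vs {len(den.epoch_index)} epochs)"
        )
    ok = den.values > EPS_DENOM
    dropped = [int(i) for i in num.epoch_index[~ok]]
    return num.values[ok] / den.values[ok], num.epoch_index[ok], dropped


def workload(theta_frontal: GFPSeries, alpha_parietal: GFPSeries):
    """Per-epoch mental-workload index (frontal theta over parietal alpha).

    Returns ``(values, epoch_index, dropped)`` where ``dropped`` lists epochs
    removed for a vanishing denominator.
    """
    return _ratio(theta_frontal, alpha_parietal)


def attention(beta_frontal: GFPSeries, theta_frontal: GFPSeries):
    """Per-epoch attention index (frontal beta over frontal theta)."""
    return _ratio(beta_frontal, theta_frontal)


def hdi(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Human Distraction Index: workload minus attention, element-wise."""
    w = np.asarray(w, dtype=float)
    a = np.asarray(a, dtype=float)
    if w.shape != a.shape:
        raise ValueError("workload and attention series are misaligned")
    return w - a


@dataclass
class BaselineStats:
    """Mean/SD of a baseline run's kept-epoch index values, for z-scoring."""

    scenario: str
    mean: float
    sd: float
    n_epochs: int

    def __post_init__(self) -> None:
        if self.n_epochs < 2:
            raise ValueError("baseline needs at least 2 epochs")
        if not self.sd > 0:
            raise ValueError("baseline SD must be positive")


def baseline_stats(values: np.ndarray, scenario: str = "") -> BaselineStats:
    """Baseline reference statistics from a focused-driving run's epochs."""
    values = np.asarray(values, dtype=float)
    return BaselineStats(
        scenario=scenario,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_epochs=len(values),
    )


def normalize(values: np.ndarray, baseline: BaselineStats,
              scenario: str | None = None) -> np.ndarray:
    """Z-score ``values`` against the scenario baseline."""
    if scenario is not None and baseline.scenario and scenario != baseline.scenario:
        raise ValueError(
            f"baseline scenario {baseline.scenario!r} does not match series "
            f"scenario {scenario!r}"
        )
    return (np.asarray(values, dtype=float) - baseline.mean) / baseline.sd


@dataclass
class IndexSeries:
    """Aligned per-epoch workload, attention and HDI, raw and normalized."""

    epoch_index: np.ndarray
    workload: np.ndarray
    attention: np.ndarray
    hdi: np.ndarray
    dropped_epochs: list[int]
    hdi_z: np.ndarray | None = None
    baseline_ref: BaselineStats | None = None

    def normalized(self, baseline: BaselineStats, scenario: str | None = None
                   ) -> "IndexSeries":
        """Copy with HDI z-scored against ``baseline``."""
        return IndexSeries(
            epoch_index=self.epoch_index,
            workload=self.workload,
            attention=self.attention,
            hdi=self.hdi,
            dropped_epochs=self.dropped_epochs,
            hdi_z=normalize(self.hdi, baseline, scenario),
            baseline_ref=baseline,
        )

    def to_frame(self, fs: float | None = None, epoch_len_s: float = 1.0
                 ) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "epoch_index": self.epoch_index,
                "time_s": self.epoch_index * epoch_len_s,
                "workload": self.workload,
                "attention": self.attention,
                "hdi": self.hdi,
            }
        )
        if self.hdi_z is not None:
            df["hdi_z"] = self.hdi_z
        return df


def compute_indices(
    theta_frontal: GFPSeries,
    alpha_parietal: GFPSeries,
    beta_frontal: GFPSeries,
) -> IndexSeries:
    """Workload, attention and HDI on the epochs where all three GFP series
    have usable denominators; dropped epochs are reported, never imputed."""
    w_vals, w_idx, w_drop = workload(theta_frontal, alpha_parietal)
    a_vals, a_idx, a_drop = attention(beta_frontal, theta_frontal)
    common = np.intersect1d(w_idx, a_idx)
    w_sel = w_vals[np.isin(w_idx, common)]
    a_sel = a_vals[np.isin(a_idx, common)]
    return IndexSeries(
        epoch_index=common,
        workload=w_sel,
        attention=a_sel,
        hdi=hdi(w_sel, a_sel),
        dropped_epochs=sorted(set(w_drop) | set(a_drop)),
    )


def segment_summary(
    values: np.ndarray,
    epoch_index: np.ndarray,
    segment_map: dict[int, str],
) -> pd.DataFrame:
    """Mean and SD of an epoch series per segment label.

    Every kept epoch must be mapped to a segment; labels with fewer than two
    epochs get SD = NaN; empty segments are simply absent.
    """
    values = np.asarray(values, dtype=float)
    epoch_index = np.asarray(epoch_index, dtype=int)
    unmapped = [int(i) for i in epoch_index if int(i) not in segment_map]
    if unmapped:
        raise KeyError(f"epochs without a segment label: {unmapped}")
    df = pd.DataFrame(
        {
            "segment": [segment_map[int(i)] for i in epoch_index],
            "value": values,
        }
    )
    out = df.groupby("segment", sort=True)["value"].agg(
        mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
        n="count",
    )
    return out.reset_index()


def write_index_table(series: IndexSeries, path: str | Path,
                      segment_map: dict[int, str] | None = None,
                      condition: str = "", scenario: str = "",
                      epoch_len_s: float = 1.0) -> None:
    """CSV export: epoch_index, time_s, workload, attention, hdi[, hdi_z],
    segment, condition, scenario."""
    df = series.to_frame(epoch_len_s=epoch_len_s)
    if segment_map is not None:
        df["segment"] = [segment_map.get(int(i), "") for i in series.epoch_index]
    df["condition"] = condition
    df["scenario"] = scenario
    df.to_csv(path, index=False)
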