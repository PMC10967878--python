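"""YAML configuration for the processing chain.

Flat dotted keys mirror the stage parameters, e.g.::

    filter:
      bandpass: {order: 5, low_hz: 2, high_hz: 30}
      notch: {center_hz: 50, q: 30}
    blink:
      channel: AFz
      z_thresh: 4.0
    reject:
      amplitude_uv: 80
      slope_uv_per_s: 20
      jump_uv: 25
      epoch_len_s: 1
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .preprocess import FilterSpec
from .rejection import ArtifactCriteria

__all__ = ["load_config", "filter_specs", "artifact_criteria"]

DEFAULTS: dict[str, Any] = {
    "filter": {
        "bandpass": {"order": 5, "low_hz": 2.0, "high_hz": 30.0},
        "notch": {"center_hz": 50.0, "q": 30.0},
    },
    "blink": {"channel": "AFz", "z_thresh": 4.0},
    "reject": {
        "amplitude_uv": 80.0,
        "slope_uv_per_s": 20.0,
        "jump_uv": 25.0,
        "epoch_len_s": 1.0,
    },
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults, optionally overridden by a YAML file."""
    cfg = DEFAULTS
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


def filter_specs(cfg: dict[str, Any]) -> tuple[FilterSpec, FilterSpec]:
    bp = cfg["filter"]["bandpass"]
    nt = cfg["filter"]["notch"]
    return (
        FilterSpec(kind="bandpass_butterworth", order=int(bp["order"]),
                   low_hz=float(bp["low_hz"]), high_hz=float(bp["high_hz"])),
        FilterSpec(kind="notch", notch_hz=float(nt["center_hz"]),
                   notch_q=float(nt["q"])),
    )


def artifact_criteria(cfg: dict[str, Any]) -> ArtifactCriteria:
    r = cfg["reject"]
    return ArtifactCriteria(
        amplitude_uv=float(r["amplitude_uv"]),
        slope_uv_per_s=float(r["slope_uv_per_s"]),
        jump_uv=float(r["jump_uv"]),
        epoch_len_s=float(r["epoch_len_s"]),
    )
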