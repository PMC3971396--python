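"""Run configuration: parameter grids, smoothing and significance levels.

A YAML/JSON file can override any field, e.g.::

    window_s: 60
    kalman: {q: 1.0e-4, r: 1.0e-2}
    sop_min_grid: [10, 30, 60]
    thresholds: {lo_pct: 5, hi_pct: 50, step_pct: 1}
    alpha_patient: 0.01
    alpha_group: 0.05
    n_train_seizures: 4
    min_train_h: 10
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ensemble import KALMAN_Q, KALMAN_R

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    window_s: float = 60.0
    kalman_q: float = KALMAN_Q
    kalman_r: float = KALMAN_R
    sop_min_grid: tuple[int, ...] = (10, 30, 60)
    threshold_lo_pct: float = 5.0
    threshold_hi_pct: float = 50.0
    threshold_step_pct: float = 1.0
    alpha_patient: float = 0.01
    alpha_group: float = 0.05
    n_train_seizures: int = 4
    min_train_h: float = 10.0
    low_bands: tuple[str, ...] = ("delta", "theta")
    high_bands: tuple[str, ...] = ("LG", "HG")
    extras: dict = field(default_factory=dict)

    def thresholds(self) -> np.ndarray:
        grid = np.arange(
            self.threshold_lo_pct,
            self.threshold_hi_pct + 0.5 * self.threshold_step_pct,
            self.threshold_step_pct,
        )
        return np.round(grid / 100.0, 6)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or JSON config file; ``None`` gives the defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    ) or {}
    kalman = data.pop("kalman", {})
    if "q" in kalman:
        cfg.kalman_q = float(kalman["q"])
    if "r" in kalman:
        cfg.kalman_r = float(kalman["r"])
    thr = data.pop("thresholds", {})
    if "lo_pct" in thr:
        cfg.threshold_lo_pct = float(thr["lo_pct"])
    if "hi_pct" in thr:
        cfg.threshold_hi_pct = float(thr["hi_pct"])
    if "step_pct" in thr:
        cfg.threshold_step_pct = float(thr["step_pct"])
    for key, value in data.items():
        if hasattr(cfg, key):
            setattr(
                cfg, key,
                tuple(value) if isinstance(value, list) else value,
            )
        else:
            cfg.extras[key] = value
    return cfg
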