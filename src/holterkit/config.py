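"""Pipeline configuration: every declared analysis constant in one place.

All values are plain scalars/lists so a config round-trips losslessly through
YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- segmentation ---
    delineation_lead: str = "II"
    min_beats_per_window: int = 3          # median support per 10-s window
    sdnn_min_nn: int = 30                  # NN beats per 5-min SDNN window
    artifact_fraction_limit: float = 0.5   # unusable window above this
    saturation_mv: float = 5.0
    nonsinus_qrs_ms: float = 120.0         # QRS width rule for non-sinus
    nonsinus_rr_frac: float = 0.20         # RR deviation rule for non-sinus

    # --- median beat / deviations ---
    beat_window_ms: tuple[float, float] = (-200.0, 452.0)  # around QRS onset
    hr_bin_width_bpm: float = 5.0
    hr_bin_min_bpm: float = 40.0
    hr_bin_max_bpm: float = 140.0
    baseline_min_segments: int = 10
    hr_match_max_bpm: float = 10.0         # nearest-bin fallback range
    st_window_ms: tuple[float, float] = (40.0, 80.0)   # after the J point
    t_window_start_ms: float = 80.0        # after QRS offset
    iso_window_ms: tuple[float, float] = (-40.0, -10.0)  # before QRS onset

    # --- ischemia rule ---
    min_event_segments: int = 3            # >= 30 s on the 10-s grid
    contiguity_rule: str = "pair_stable"   # or "any_pair"
    cutoff_grid_mv: tuple[float, float, float] = (0.0, 0.5, 0.005)
    burden_flag_s_per_day: float = 60.0
    concurrency_window_min: float = 30.0
    symptom_dedup_min: float = 10.0
    covadis_reference_mv: float = 0.1

    # --- circadian / resting ---
    day_usable_min_fraction: float = 0.5
    bin_hours: float = 3.0
    bin_min_windows: int = 10
    resting_band: tuple[str, str] = ("06:30", "08:30")
    resting_target_bpm: float = 75.0
    resting_symptom_margin_min: float = 15.0
    qtc_prolonged_ms: dict = field(
        default_factory=lambda: {"F": 460.0, "M": 450.0})

    # --- statistics ---
    alpha: float = 0.05
    shapiro_alpha: float = 0.05
    bootstrap_samples: int = 1000
    bootstrap_stratified: bool = True
    auc_score: str = "burden"              # "burden" (continuous) or "flag"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(getattr(cls(), f.name), tuple):
                    v = tuple(v)
                kwargs[f.name] = v
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.hr_bin_width_bpm <= 0 or self.hr_bin_min_bpm >= self.hr_bin_max_bpm:
            raise ValueError("invalid heart-rate bin definition")
        if self.min_event_segments < 1:
            raise ValueError("min_event_segments must be >= 1")
        if self.contiguity_rule not in ("pair_stable", "any_pair"):
            raise ValueError("contiguity_rule must be pair_stable or any_pair")
        lo, hi, step = self.cutoff_grid_mv
        if not (0 <= lo < hi and step > 0):
            raise ValueError("invalid cutoff grid")
        if not (0 < self.alpha < 1 and 0 < self.shapiro_alpha < 1):
            raise ValueError("alpha out of range")
        if self.auc_score not in ("burden", "flag"):
            raise ValueError("auc_score must be burden or flag")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def hash(self) -> str:
        """Short digest of the config, stamped onto output files."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def cutoffs(self):
        import numpy as np
        lo, hi, step = self.cutoff_grid_mv
        n = int(round((hi - lo) / step))
        return np.round(lo + step * np.arange(n + 1), 6)


DEFAULT_CONFIG = PipelineConfig()
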