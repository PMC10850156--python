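"""Structured run configuration.

Every numeric rule used by the pipeline lives here as an overridable
default, so the constants that define the analysis (moving-window
length, behavioral speed cut-offs, puncta threshold, ...) are visible,
serializable and testable in one place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from fiberbehav.errors import ParameterError


@dataclass
class Thresholds:
    """Numeric decision rules for behavioral and cellular classification.

    Units: speeds in cm/s, durations in seconds, distances in cm,
    motion in percent body-pixel change per frame, puncta in counts.
    """

    immobility_speed: float = 6.0        # speed < 6 cm/s ...
    immobility_motion: float = 1.0       # ... and motion < 1 %
    immobility_min_frames: int = 15      # bout must exceed 15 frames (strict >)
    locomotion_speed: float = 6.0        # speed > 60 mm/s
    locomotion_min_distance: float = 10.0  # bouts shorter than 100 mm discarded
    pause_speed: float = 3.0             # pause: speed < 3 cm/s ...
    pause_min_duration: float = 1.0      # ... for at least 1 s
    focused_gap: float = 5.0             # successive head-dips within 5 s
    zone_fraction: float = 0.25          # thigmotactic periphery = outer 25 %
    zone_mode: str = "linear"            # 25 % of linear extent vs of area
    puncta_threshold: int = 4            # >= 4 puncta marks a positive cell
    fdr_alpha: float = 0.05              # BH-adjusted significance level
    stability_ratio: float = 5.0         # baseline rate max/min > 5x discards unit


@dataclass
class SessionConfig:
    """Acquisition and processing parameters for one recording session."""

    sample_rate_target: float = 100.0    # Hz, uniform grid after resampling
    lowpass_cutoff: float = 2.0          # Hz
    zscore_window: float = 60.0          # s, moving window for (f-f0)/f1
    epoch_length: float = 180.0          # s, 3-min blocks
    epoch_design: tuple[str, ...] = ("Pre", "ON", "OFF", "ON", "OFF")
    frame_rate: float | None = None      # Hz; tracking-dependent, no default
    arena_size: tuple[float, float] = (50.0, 50.0)  # cm (open field)
    motion_fit_degree: int = 1           # polynomial degree for 405-nm regression
    baseline_window: tuple[float, float] = (-5.0, -3.0)  # s, event-triggered baseline
    extremum_window: tuple[float, float] = (0.0, 3.0)    # s, corrected max/min
    event_pre: float = 5.0               # s before behavior initiation
    event_post: float = 5.0              # s after behavior initiation
    thresholds: Thresholds = field(default_factory=Thresholds)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        if isinstance(self.epoch_design, list):
            self.epoch_design = tuple(self.epoch_design)
        if isinstance(self.arena_size, list):
            self.arena_size = tuple(self.arena_size)
        if isinstance(self.baseline_window, list):
            self.baseline_window = tuple(self.baseline_window)
        if isinstance(self.extremum_window, list):
            self.extremum_window = tuple(self.extremum_window)
        self.validate()

    def validate(self) -> None:
        for name in ("sample_rate_target", "lowpass_cutoff", "zscore_window",
                     "epoch_length", "event_pre", "event_post"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.epoch_design or any(not lbl for lbl in self.epoch_design):
            raise ParameterError("epoch_design labels must be nonempty")
        if self.frame_rate is not None and self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0 when set")
        if any(s <= 0 for s in self.arena_size):
            raise ParameterError("arena dimensions must be > 0")
        if self.thresholds.zone_mode not in ("linear", "area"):
            raise ParameterError("zone_mode must be 'linear' or 'area'")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d is None:
            d = {}
        if not isinstance(d, dict):
            raise ParameterError(f"config file {path} must be a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the full configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()
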