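"""Run configuration: every threshold and tolerance of the pipeline in one place.

Defaults are the values used throughout: a 30 deg/s velocity criterion sustained
for 10 ms marks saccade onset, events are kept when 1 deg < magnitude < 40 deg
and duration > 15 ms with plausibility checks on initial/terminal and
first-quartile speed, position signals are smoothed with a 3rd-order
Savitzky-Golay filter over 15 samples, and scene cuts are transitions whose
frame-difference metric exceeds the clip mean plus one standard deviation.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # --- preprocessing ---
    blink_speed_threshold_deg_s: float = 30.0  # deg/s; blink-edge cleanup criterion
    blink_march_cap_ms: float = 50.0  # ms; max span invalidated on each side of a gap
    savgol_window: int = 15  # samples
    savgol_order: int = 3
    savgol_derivative: bool = False  # True: speed from the filter's analytic derivative

    # --- saccade detection ---
    onset_threshold_deg_s: float = 30.0  # deg/s; "speed exceeded" criterion
    min_above_ms: float = 10.0  # ms the speed must stay above threshold
    magnitude_min_deg: float = 1.0
    magnitude_max_deg: float = 40.0
    duration_min_ms: float = 15.0
    initial_speed_max_deg_ms: float = 0.075  # deg/ms at the onset sample
    terminal_speed_max_deg_ms: float = 0.3  # deg/ms at the offset sample
    quartile_peak_fraction: float = 0.15  # first-quartile speed >= fraction * peak
    horizontal_band_deg: float = 5.0  # orientation: within this of 0/180
    vertical_band_deg: float = 22.0  # orientation: within this of 90/270

    # --- metrics ---
    curvature_variant: str = "as_written"  # or "perpendicular"
    fit_max_iterations: int = 200
    fit_tolerance: float = 1e-10
    velocity_residual: str = "discrete"  # or "analytic"
    displacement_mode: str = "from_start"  # or "cumulative"

    # --- scene cuts ---
    cut_k_sd: float = 1.0  # threshold = mean + k_sd * sd of the metric
    cut_min_gap_frames: int = 5
    fade_reject: bool = True
    cut_epsilon: float = 1e-6  # guards log(0) for identical frames

    # --- plumbing ---
    seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "blink_speed_threshold_deg_s",
            "blink_march_cap_ms",
            "savgol_window",
            "savgol_order",
            "onset_threshold_deg_s",
            "min_above_ms",
            "magnitude_min_deg",
            "magnitude_max_deg",
            "duration_min_ms",
            "initial_speed_max_deg_ms",
            "terminal_speed_max_deg_ms",
            "quartile_peak_fraction",
            "horizontal_band_deg",
            "vertical_band_deg",
            "fit_max_iterations",
            "fit_tolerance",
            "cut_epsilon",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise FormatError(f"RunConfig.{name} must be strictly positive")
        if self.curvature_variant not in ("as_written", "perpendicular"):
            raise FormatError("curvature_variant must be 'as_written' or 'perpendicular'")
        if self.velocity_residual not in ("discrete", "analytic"):
            raise FormatError("velocity_residual must be 'discrete' or 'analytic'")
        if self.displacement_mode not in ("from_start", "cumulative"):
            raise FormatError("displacement_mode must be 'from_start' or 'cumulative'")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # unit conversion helpers; internal speed unit is deg/ms
    @property
    def onset_threshold_deg_ms(self) -> float:
        return self.onset_threshold_deg_s / 1000.0

    @property
    def blink_speed_threshold_deg_ms(self) -> float:
        return self.blink_speed_threshold_deg_s / 1000.0
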