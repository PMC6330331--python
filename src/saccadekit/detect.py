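"""Saccade segmentation and inclusion rules.

A saccade candidate is a maximal run of samples whose speed exceeds 30 deg/s
(0.03 deg/ms) lasting at least 10 ms; onset is the first sample of the run and
offset the last sample before speed drops back below threshold. Candidates are
then screened: magnitude must lie strictly between 1 and 40 deg (the upper
bound being roughly the diagonal of a typical display, the lower excluding
microsaccades), duration strictly above 15 ms, speed at the onset sample below
0.075 deg/ms, speed at the offset sample below 0.3 deg/ms (eye-position
overshoots and glissades), and the speed at the first quarter of the event at
least 0.15x the peak (rejecting slow, pursuit-like ramps). Each rejected
candidate carries exactly one reason: the first failing rule in that order,
with a boundary check first (events touching the trace edge are untrustworthy
on both kinematics and the profile fit).

Orientation is classified from the start-to-end direction under the y-up
convention: horizontal within 5 deg of 0/180, vertical within 22 deg of
90/270, otherwise oblique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import DegeneratePredictorError, InsufficientDataError
from .metrics import VelocityProfileFit
from .preprocess import SpeedTrace

__all__ = [
    "SaccadeEvent",
    "segment",
    "apply_filters",
    "classify_orientation",
    "main_sequence",
    "detect_saccades",
    "REJECTION_REASONS",
]

REJECTION_REASONS = (
    "boundary",
    "magnitude_low",
    "magnitude_high",
    "duration_short",
    "initial_velocity",
    "terminal_velocity",
    "slow_first_quartile",
)


@dataclass
class SaccadeEvent:
    """One detected saccade and its kinematics.

    Onset/offset are in ms on the trace's own time base; ``session_offset_ms``
    is the onset time from session start. ``curvature`` and ``profile_fit``
    are filled by :mod:`saccadekit.metrics`, ``inflight_cut`` by
    :mod:`saccadekit.cuts`.
    """

    onset_ms: float
    offset_ms: float
    magnitude_deg: float
    path_length_deg: float
    peak_velocity_deg_ms: float
    direction_deg: float
    orientation: str
    leftward: bool
    downward: bool
    trace_id: str = ""
    subject_id: str | None = None
    clip_id: str | None = None
    session_offset_ms: float = 0.0
    onset_idx: int = -1
    offset_idx: int = -1
    curvature: float | None = None
    profile_fit: VelocityProfileFit | None = None
    inflight_cut: bool = False
    rejection_reason: str | None = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def classify_orientation(
    direction_deg: float,
    horizontal_band: float = 5.0,
    vertical_band: float = 22.0,
) -> tuple[str, bool, bool]:
    """Map a direction angle (deg, CCW from rightward, [0, 360)) to
    (orientation, leftward, downward). Band edges are inclusive."""
    d = float(direction_deg) % 360.0

    def _dist(a: float, b: float) -> float:
        return abs((a - b + 180.0) % 360.0 - 180.0)

    if min(_dist(d, 0.0), _dist(d, 180.0)) <= horizontal_band:
        orientation = "horizontal"
    elif min(_dist(d, 90.0), _dist(d, 270.0)) <= vertical_band:
        orientation = "vertical"
    else:
        orientation = "oblique"
    leftward = 90.0 < d < 270.0
    downward = 180.0 < d < 360.0
    return orientation, leftward, downward


def _make_event(speed: SpeedTrace, i0: int, i1: int, config: RunConfig) -> SaccadeEvent:
    x = speed.smoothed_x
    y = speed.smoothed_y
    dx = x[i1] - x[i0]
    dy = y[i1] - y[i0]
    seg_x = x[i0 : i1 + 1]
    seg_y = y[i0 : i1 + 1]
    path = float(np.sum(np.hypot(np.diff(seg_x), np.diff(seg_y))))
    direction = float(np.degrees(np.arctan2(dy, dx)) % 360.0)
    orientation, leftward, downward = classify_orientation(
        direction, config.horizontal_band_deg, config.vertical_band_deg
    )
    onset_ms = float(speed.sample_times[i0])
    return SaccadeEvent(
        onset_ms=onset_ms,
        offset_ms=float(speed.sample_times[i1]),
        magnitude_deg=float(np.hypot(dx, dy)),
        path_length_deg=path,
        peak_velocity_deg_ms=float(np.max(speed.speed[i0 : i1 + 1])),
        direction_deg=direction,
        orientation=orientation,
        leftward=leftward,
        downward=downward,
        trace_id=speed.trace_id,
        session_offset_ms=speed.session_offset + onset_ms - float(speed.sample_times[0]),
        onset_idx=i0,
        offset_idx=i1,
    )


def segment(
    speed: SpeedTrace,
    onset_threshold_deg_s: float = 30.0,
    min_above_ms: float = 10.0,
    config: RunConfig | None = None,
) -> list[SaccadeEvent]:
    """Candidate saccades: maximal supra-threshold runs lasting >= min_above_ms.

    Comparisons follow the wording: strictly above threshold to start
    ("exceeded"), a single strictly-below sample ends the run ("went below").
    Returns time-ordered, non-overlapping candidates; an empty list is valid.
    """
    config = config or RunConfig(
        onset_threshold_deg_s=onset_threshold_deg_s, min_above_ms=min_above_ms
    )
    thr = onset_threshold_deg_s / 1000.0
    above = speed.speed > thr
    if not above.any():
        return []
    dt = speed.dt_ms
    min_len = int(np.ceil(min_above_ms / dt))
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    events = []
    for run in np.split(idx, breaks):
        if len(run) >= min_len:
            events.append(_make_event(speed, int(run[0]), int(run[-1]), config))
    return events


def apply_filters(
    candidates: list[SaccadeEvent],
    speed: SpeedTrace,
    config: RunConfig | None = None,
) -> tuple[list[SaccadeEvent], list[SaccadeEvent]]:
    """Partition candidates into (accepted, rejected-with-reason).

    Rules, in order: boundary contact; 1 deg < magnitude < 40 deg; duration
    > 15 ms; onset-sample speed < 0.075 deg/ms; offset-sample speed
    < 0.3 deg/ms; speed at onset + floor(duration/4) samples >= 0.15 * peak.
    """
    config = config or RunConfig()
    n = len(speed)
    accepted: list[SaccadeEvent] = []
    rejected: list[SaccadeEvent] = []
    for ev in candidates:
        reason = None
        n_samp = ev.offset_idx - ev.onset_idx + 1
        quartile_idx = ev.onset_idx + n_samp // 4
        if ev.onset_idx <= 0 or ev.offset_idx >= n - 1:
            reason = "boundary"
        elif ev.magnitude_deg <= config.magnitude_min_deg:
            reason = "magnitude_low"
        elif ev.magnitude_deg >= config.magnitude_max_deg:
            reason = "magnitude_high"
        elif ev.duration_ms <= config.duration_min_ms:
            reason = "duration_short"
        elif speed.speed[ev.onset_idx] >= config.initial_speed_max_deg_ms:
            reason = "initial_velocity"
        elif speed.speed[ev.offset_idx] >= config.terminal_speed_max_deg_ms:
            reason = "terminal_velocity"
        elif speed.speed[quartile_idx] < config.quartile_peak_fraction * ev.peak_velocity_deg_ms:
            reason = "slow_first_quartile"
        if reason is None:
            accepted.append(ev)
        else:
            ev.rejection_reason = reason
            rejected.append(ev)
    return accepted, rejected


def main_sequence(events: list[SaccadeEvent]):
    """Per-event (magnitude, duration, peak velocity) plus the log-log OLS fit
    of peak velocity on magnitude (base-10). Returns (table, slope, intercept).
    """
    if len(events) < 3:
        raise InsufficientDataError(f"main sequence needs >= 3 events, got {len(events)}")
    mag = np.array([ev.magnitude_deg for ev in events])
    dur = np.array([ev.duration_ms for ev in events])
    pv = np.array([ev.peak_velocity_deg_ms for ev in events])
    lx = np.log10(mag)
    ly = np.log10(pv)
    if np.ptp(lx) == 0:
        raise DegeneratePredictorError("all magnitudes identical: main-sequence fit is degenerate")
    slope, intercept = np.polyfit(lx, ly, 1)
    table = np.column_stack([mag, dur, pv])
    return table, float(slope), float(intercept)


def detect_saccades(
    speed: SpeedTrace, config: RunConfig | None = None
) -> tuple[list[SaccadeEvent], list[SaccadeEvent]]:
    """Segment then filter: returns (accepted, rejected)."""
    config = config or RunConfig()
    candidates = segment(speed, config.onset_threshold_deg_s, config.min_above_ms, config)
    return apply_filters(candidates, speed, config)
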