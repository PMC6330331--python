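"""Signal conditioning ahead of saccade detection.

The fixed order is: excise blink-adjacent artifacts, cubic-spline interpolate
the missing spans, Savitzky-Golay smooth, then differentiate to speed. Video
eye trackers corrupt the samples flanking a blink (the lid occludes the pupil
progressively), which shows up as spurious high-velocity excursions; those
samples are invalidated when their local speed exceeds 30 deg/s and then
bridged by the same spline interpolation used for the blink gap itself.

Internal speed unit is deg/ms throughout (30 deg/s = 0.03 deg/ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .config import RunConfig
from .errors import InsufficientDataError
from .gaze_io import GazeTrace

__all__ = [
    "SpeedTrace",
    "excise_blinks",
    "interpolate_gaps",
    "smooth",
    "compute_speed",
    "preprocess_trace",
]


@dataclass
class SpeedTrace:
    """Smoothed positions plus the planar speed (norm of the velocity vector)."""

    sample_times: np.ndarray  # ms
    speed: np.ndarray  # deg/ms, >= 0
    smoothed_x: np.ndarray
    smoothed_y: np.ndarray
    interpolated_mask: np.ndarray  # True where the position was reconstructed
    trace_id: str = ""
    session_offset: float = 0.0

    def __len__(self) -> int:
        return len(self.sample_times)

    @property
    def dt_ms(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])


def _raw_speed(trace: GazeTrace) -> np.ndarray:
    """Per-sample speed from one-step differences (deg/ms), used only for the
    blink-edge cleanup where central differences would straddle the gap."""
    dt = trace.dt_ms
    dx = np.diff(trace.x_pos)
    dy = np.diff(trace.y_pos)
    return np.hypot(dx, dy) / dt


def excise_blinks(trace: GazeTrace, speed_threshold_deg_s: float = 30.0, cap_ms: float = 50.0) -> GazeTrace:
    """Invalidate high-velocity samples flanking each tracker-reported gap.

    From each edge of every invalid run, march outward through valid samples
    while the speed of the step just taken exceeds ``speed_threshold_deg_s``,
    invalidating as we go, up to ``cap_ms`` per side. Samples already invalid
    stay invalid. Gaps at the trace boundary are processed on their one
    interior side only.
    """
    valid = trace.valid.copy()
    if not valid.any():
        raise InsufficientDataError("trace has no valid samples")
    if valid.all():
        return trace.copy()

    thr = speed_threshold_deg_s / 1000.0  # deg/ms
    dt = trace.dt_ms
    cap = max(1, int(round(cap_ms / dt)))
    step_speed = _raw_speed(trace)  # step_speed[i] = speed of step i -> i+1
    n = len(trace)

    # locate invalid runs on the ORIGINAL mask so enlargement does not cascade
    orig = trace.valid
    idx = np.flatnonzero(~orig)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1) if idx.size else []
    for run in runs:
        start, stop = run[0], run[-1]
        # leading edge: march left from start-1; a sample's speed is taken on
        # its away-from-gap step (the gap side holds undefined positions)
        i = start - 1
        taken = 0
        while i >= 1 and taken < cap and orig[i] and step_speed[i - 1] > thr:
            valid[i] = False
            i -= 1
            taken += 1
        # trailing edge: march right from stop+1
        i = stop + 1
        taken = 0
        while i <= n - 2 and taken < cap and orig[i] and step_speed[i] > thr:
            valid[i] = False
            i += 1
            taken += 1
    out = trace.copy()
    out.valid = valid
    if not valid.any():
        raise InsufficientDataError("blink excision removed every sample")
    return out


def interpolate_gaps(trace: GazeTrace) -> GazeTrace:
    """Replace invalid spans with natural cubic-spline values fit on the valid
    samples; edge gaps (no bracketing data) are filled by holding the nearest
    valid value. All samples are marked valid afterwards; the returned trace
    carries the replaced-sample mask as ``trace.interpolated_mask``."""
    valid = trace.valid
    n_valid = int(valid.sum())
    if n_valid < 4:
        raise InsufficientDataError(f"need >= 4 valid samples to interpolate, have {n_valid}")
    out = trace.copy()
    mask = ~valid
    if mask.any():
        t = trace.sample_times
        tv = t[valid]
        for arr in (out.x_pos, out.y_pos):
            spline = CubicSpline(tv, arr[valid], bc_type="natural")
            interior = mask & (t >= tv[0]) & (t <= tv[-1])
            arr[interior] = spline(t[interior])
            arr[mask & (t < tv[0])] = arr[valid][0]
            arr[mask & (t > tv[-1])] = arr[valid][-1]
    out.valid = np.ones(len(trace), dtype=bool)
    out.interpolated_mask = mask  # type: ignore[attr-defined]
    return out


def smooth(trace: GazeTrace, order: int = 3, window: int = 15) -> GazeTrace:
    """Savitzky-Golay smooth x and y independently.

    Edge samples are handled by refitting the polynomial on the truncated
    one-sided window (scipy's ``mode='interp'``), so a polynomial of degree
    <= ``order`` passes through unchanged everywhere including the edges.
    """
    if len(trace) < window:
        raise InsufficientDataError(f"trace length {len(trace)} < smoothing window {window}")
    out = trace.copy()
    out.x_pos = savgol_filter(trace.x_pos, window, order, mode="interp")
    out.y_pos = savgol_filter(trace.y_pos, window, order, mode="interp")
    if hasattr(trace, "interpolated_mask"):
        out.interpolated_mask = trace.interpolated_mask  # type: ignore[attr-defined]
    return out


def compute_speed(trace: GazeTrace, savgol_derivative: bool = False, order: int = 3, window: int = 15) -> SpeedTrace:
    """Speed as the norm of the planar velocity vector, in deg/ms.

    Default differentiation is central differences on the (already smoothed)
    positions, one-sided at the edges. ``savgol_derivative=True`` instead takes
    the Savitzky-Golay filter's analytic first derivative of the raw positions.
    """
    t = trace.sample_times
    sx, sy = trace.x_pos, trace.y_pos
    if savgol_derivative:
        if len(trace) < window:
            raise InsufficientDataError(f"trace length {len(trace)} < smoothing window {window}")
        dt = trace.dt_ms
        sx = savgol_filter(trace.x_pos, window, order, mode="interp")
        sy = savgol_filter(trace.y_pos, window, order, mode="interp")
        vx = savgol_filter(trace.x_pos, window, order, deriv=1, delta=dt, mode="interp")
        vy = savgol_filter(trace.y_pos, window, order, deriv=1, delta=dt, mode="interp")
    else:
        vx = np.gradient(trace.x_pos, t)
        vy = np.gradient(trace.y_pos, t)
    mask = getattr(trace, "interpolated_mask", np.zeros(len(trace), dtype=bool))
    return SpeedTrace(
        sample_times=t.copy(),
        speed=np.hypot(vx, vy),
        smoothed_x=np.asarray(sx, dtype=float).copy(),
        smoothed_y=np.asarray(sy, dtype=float).copy(),
        interpolated_mask=np.asarray(mask, dtype=bool),
        trace_id=trace.trace_id,
        session_offset=trace.session_offset,
    )


def preprocess_trace(trace: GazeTrace, config: RunConfig | None = None) -> SpeedTrace:
    """The full, order-fixed conditioning pipeline: excise -> interpolate ->
    smooth -> speed."""
    config = config or RunConfig()
    cleaned = excise_blinks(trace, config.blink_speed_threshold_deg_s, config.blink_march_cap_ms)
    filled = interpolate_gaps(cleaned)
    if config.savgol_derivative:
        return compute_speed(filled, savgol_derivative=True, order=config.savgol_order, window=config.savgol_window)
    smoothed = smooth(filled, order=config.savgol_order, window=config.savgol_window)
    return compute_speed(smoothed)
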