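"""Scene-cut (shot-change) detection and in-flight saccade flagging.

For each consecutive frame pair the metric is the log of the mean absolute
pixel difference (normalized by the frame's pixel count), with a small epsilon
guarding log(0) on identical frames:

    m_i = log(eps + sum_pixels |F_{i+1} - F_i| / N_pixels)

A transition is a cut candidate when its metric exceeds the clip's mean plus
``k_sd`` standard deviations (both computed over all transitions of the clip,
cuts included). Candidates closer than ``min_gap_frames`` are reduced to the
one with the larger metric. Gradual fades produce runs of near-identical
supra-threshold transitions; when ``fade_reject`` is on, any candidate lying
in a run of three or more consecutive supra-threshold transitions whose
metrics agree pairwise within 10% is discarded. The cut time is that of the
LATER frame of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, SaccadeKitError
from .gaze_io import ClipFrames

__all__ = ["SceneCutSet", "frame_diff_metric", "detect_cuts", "flag_inflight", "detect_clip_cuts"]


@dataclass
class SceneCutSet:
    """Per-transition metric, adaptive threshold and the accepted cuts."""

    metric: np.ndarray  # length n_frames - 1; metric[i] is for frames (i, i+1)
    threshold: float
    cut_frames: np.ndarray  # indices of the later frame of each accepted cut
    cut_times_ms: np.ndarray
    rejected_fades: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def frame_diff_metric(clip: ClipFrames, epsilon: float = 1e-6) -> np.ndarray:
    """Log mean-absolute-difference series, one value per frame transition."""
    frames = clip.frames
    if frames.ndim != 3:
        raise FormatError("clip frames must be a (n, h, w) stack")
    diffs = np.abs(np.diff(frames, axis=0))
    mad = diffs.reshape(diffs.shape[0], -1).mean(axis=1)
    return np.log(epsilon + mad)


def detect_cuts(
    metric: np.ndarray,
    frame_rate: float,
    k_sd: float = 1.0,
    min_gap_frames: int = 5,
    fade_reject: bool = True,
) -> SceneCutSet:
    """Threshold the metric series and return the accepted cuts.

    A zero-variance series yields no cuts (nothing stands out). Frame index
    reported is the later frame of the transition pair; its time is
    ``index / frame_rate`` in ms.
    """
    metric = np.asarray(metric, dtype=float)
    if len(metric) < 2:
        raise FormatError("metric series needs at least 2 transitions")
    mean = float(metric.mean())
    sd = float(metric.std())
    threshold = mean + k_sd * sd
    if sd == 0.0:
        return SceneCutSet(metric, threshold, np.array([], dtype=int), np.array([]))
    above = np.flatnonzero(metric > threshold)

    rejected_fades: list[int] = []
    if fade_reject and above.size:
        # runs of >= 3 consecutive supra-threshold transitions with pairwise
        # metric agreement within 10% are gradual-ramp signatures
        breaks = np.flatnonzero(np.diff(above) > 1) + 1
        keep = []
        for run in np.split(above, breaks):
            vals = metric[run]
            scale = np.max(np.abs(vals))
            if len(run) >= 3 and scale > 0 and (np.ptp(vals) / scale) < 0.10:
                rejected_fades.extend(int(i) for i in run)
            else:
                keep.extend(int(i) for i in run)
        above = np.array(keep, dtype=int)

    # enforce the minimum gap, keeping the larger metric of any close pair
    accepted: list[int] = []
    for i in sorted(above, key=lambda i: (-metric[i], i)):
        if all(abs(i - j) >= min_gap_frames for j in accepted):
            accepted.append(i)
    accepted.sort()

    cut_frames = np.array([i + 1 for i in accepted], dtype=int)
    cut_times = cut_frames / frame_rate * 1000.0
    return SceneCutSet(metric, threshold, cut_frames, cut_times, np.array(sorted(rejected_fades), dtype=int))


def detect_clip_cuts(
    clip: ClipFrames,
    k_sd: float = 1.0,
    min_gap_frames: int = 5,
    fade_reject: bool = True,
    epsilon: float = 1e-6,
) -> SceneCutSet:
    """Convenience: metric + thresholding in one call."""
    return detect_cuts(frame_diff_metric(clip, epsilon), clip.frame_rate, k_sd, min_gap_frames, fade_reject)


def flag_inflight(events, cuts: SceneCutSet, clip_offset_ms: float = 0.0):
    """Set ``inflight_cut`` on every event whose [onset, offset] interval (in
    session time, closed at both ends) contains a cut time. Returns the events
    for chaining."""
    times = np.asarray(cuts.cut_times_ms, dtype=float) + clip_offset_ms
    if np.any(np.diff(times) < 0):
        raise SaccadeKitError("cut times must be non-decreasing")
    for ev in events:
        onset = ev.session_offset_ms
        offset = onset + ev.duration_ms
        ev.inflight_cut = bool(np.any((times >= onset) & (times <= offset)))
    return events
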