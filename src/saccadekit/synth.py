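"""Synthetic gaze sessions and video clips with exact ground truth.

Sessions emulate 1 kHz video-oculography during natural viewing: fixations
with small positional jitter, saccades whose along-track displacement follows
the compressed exponential model (so magnitude/duration/peak velocity obey a
main-sequence-like relation), optional trajectory curvature, blinks (tracker
dropouts flanked by high-velocity lid artifacts), low-velocity smooth-pursuit
drift, and additive white Gaussian measurement noise.

Curvature is injected as a single-parameter symmetric bow: the perpendicular
offset from the straight chord is ``bow_amplitude * 4 s (1 - s)`` where ``s``
is normalized along-track progress, so it vanishes at both endpoints and peaks
at ``bow_amplitude`` degrees mid-flight. Real curved saccades are not this
tidy; the bow is a measurement stand-in, monotone in every curvature metric,
not an oculomotor model.

Clips are stacks of uniform-intensity frames with i.i.d. Gaussian pixel noise;
scene cuts are abrupt mean-level steps of at least 40 gray levels and fades
are linear level ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .errors import SpecError
from .gaze_io import ClipFrames, GazeTrace

__all__ = [
    "SaccadeSpec",
    "SessionSpec",
    "GroundTruthSaccade",
    "GroundTruth",
    "make_saccade_trajectory",
    "make_session",
    "make_clip",
    "standard_session_spec",
]

#: Samples of lid artifact on each side of a simulated blink gap.
BLINK_FLANK_SAMPLES = 5


@dataclass
class SaccadeSpec:
    """One scripted saccade: onset (ms), magnitude p1 (deg), direction (deg,
    CCW from rightward), model time scale p2 (ms) and shape p3, signed bow
    amplitude (deg, positive = left of travel), optional explicit start."""

    onset_ms: float
    magnitude: float
    direction: float
    p2: float
    p3: float
    bow_amplitude: float = 0.0
    start_x: float | None = None
    start_y: float | None = None

    def __post_init__(self) -> None:
        if self.magnitude <= 0 or self.p2 <= 0 or self.p3 <= 0:
            raise SpecError("magnitude, p2 and p3 must all be positive")

    @property
    def duration_ms(self) -> float:
        return model.duration_ms(self.p2, self.p3)


@dataclass
class SessionSpec:
    """Scripted session: saccades, blinks (start, duration), pursuit segments
    (start, duration, velocity deg/s, direction deg) and two noise levels."""

    duration_ms: float
    sampling_rate: float = 1000.0
    saccades: list[SaccadeSpec] = field(default_factory=list)
    fixation_noise_sd: float = 0.0  # deg, jitter added during fixation only
    measurement_noise_sd: float = 0.0  # deg, added to every sample
    blinks: list[tuple[float, float]] = field(default_factory=list)
    pursuits: list[tuple[float, float, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixation_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise SpecError("noise standard deviations must be >= 0")
        intervals = [(s.onset_ms, s.onset_ms + s.duration_ms, "saccade") for s in self.saccades]
        intervals += [(b[0], b[0] + b[1], "blink") for b in self.blinks]
        intervals += [(p[0], p[0] + p[1], "pursuit") for p in self.pursuits]
        intervals.sort()
        for (a0, a1, akind), (b0, b1, bkind) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise SpecError(
                    f"overlapping events: {akind} [{a0}, {a1}) and {bkind} [{b0}, {b1})"
                )
        for a0, a1, kind in intervals:
            if a0 < 0 or a1 > self.duration_ms:
                raise SpecError(f"{kind} [{a0}, {a1}) outside session [0, {self.duration_ms})")


@dataclass
class GroundTruthSaccade:
    onset_ms: float
    offset_ms: float
    magnitude: float
    direction: float
    p1: float
    p2: float
    p3: float
    bow_amplitude: float
    start_x: float
    start_y: float


@dataclass
class GroundTruth:
    """Exact labels of everything the generator placed."""

    saccades: list[GroundTruthSaccade] = field(default_factory=list)
    blinks: list[tuple[float, float]] = field(default_factory=list)
    pursuits: list[tuple[float, float, float, float]] = field(default_factory=list)
    cut_frames: list[int] = field(default_factory=list)
    fade_spans: list[tuple[int, int]] = field(default_factory=list)


def make_saccade_trajectory(spec: SaccadeSpec, rate: float = 1000.0):
    """Sample one saccade path at ``rate`` Hz.

    Returns (t_ms, x, y): along-track displacement follows the compressed
    exponential, the perpendicular offset is the symmetric bow, and the event
    is truncated at 99.9% of the asymptotic amplitude. The first sample sits
    exactly at the start position.
    """
    if rate <= 0:
        raise SpecError("sampling rate must be positive")
    dt = 1000.0 / rate
    t_end = spec.duration_ms
    n = max(int(np.floor(t_end / dt)), 3)
    t = np.arange(n + 1) * dt
    f = model.displacement(t, spec.magnitude, spec.p2, spec.p3)
    s = f / spec.magnitude
    perp = spec.bow_amplitude * 4.0 * s * (1.0 - s)
    theta = np.radians(spec.direction)
    ux, uy = np.cos(theta), np.sin(theta)
    nx, ny = -uy, ux  # left of travel
    x0 = 0.0 if spec.start_x is None else spec.start_x
    y0 = 0.0 if spec.start_y is None else spec.start_y
    x = x0 + f * ux + perp * nx
    y = y0 + f * uy + perp * ny
    return t, x, y


def make_session(spec: SessionSpec) -> tuple[GazeTrace, GroundTruth]:
    """Render a scripted session to a gaze trace plus its exact ground truth.

    Deterministic for a fixed seed. Fixations hold the current position (plus
    jitter); saccades and pursuits move it; blinks invalidate their span and
    superimpose 40-100 deg/s position excursions on the five flanking samples
    each side, mimicking lid-occlusion artifacts.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1000.0 / spec.sampling_rate
    n = int(round(spec.duration_ms / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    valid = np.ones(n, dtype=bool)
    moving = np.zeros(n, dtype=bool)  # samples inside a saccade or pursuit

    events: list[tuple[float, str, object]] = [(s.onset_ms, "saccade", s) for s in spec.saccades]
    events += [(p[0], "pursuit", p) for p in spec.pursuits]
    events.sort(key=lambda e: e[0])

    truth = GroundTruth(blinks=list(spec.blinks), pursuits=list(spec.pursuits))
    pos = np.array([0.0, 0.0])
    if events and events[0][1] == "saccade" and events[0][2].start_x is not None:
        pos = np.array([events[0][2].start_x, events[0][2].start_y])
    cursor = 0  # next sample to fill
    for onset, kind, payload in events:
        i0 = int(round(onset / dt))
        x[cursor:i0] = pos[0]
        y[cursor:i0] = pos[1]
        if kind == "saccade":
            s: SaccadeSpec = payload
            if s.start_x is not None:  # explicit start: position jumps at onset
                pos = np.array([s.start_x, s.start_y])
            st, sx, sy = make_saccade_trajectory(
                SaccadeSpec(
                    onset_ms=s.onset_ms,
                    magnitude=s.magnitude,
                    direction=s.direction,
                    p2=s.p2,
                    p3=s.p3,
                    bow_amplitude=s.bow_amplitude,
                    start_x=pos[0],
                    start_y=pos[1],
                ),
                spec.sampling_rate,
            )
            i1 = min(i0 + len(st), n)
            x[i0:i1] = sx[: i1 - i0]
            y[i0:i1] = sy[: i1 - i0]
            moving[i0:i1] = True
            pos = np.array([sx[-1], sy[-1]])
            truth.saccades.append(
                GroundTruthSaccade(
                    onset_ms=onset,
                    offset_ms=onset + st[-1],
                    magnitude=s.magnitude,
                    direction=s.direction,
                    p1=s.magnitude,
                    p2=s.p2,
                    p3=s.p3,
                    bow_amplitude=s.bow_amplitude,
                    start_x=pos[0] - (sx[-1] - sx[0]),
                    start_y=pos[1] - (sy[-1] - sy[0]),
                )
            )
            cursor = i1
        else:
            start, dur, vel, direction = payload
            i1 = min(i0 + int(round(dur / dt)), n)
            theta = np.radians(direction)
            step = vel / 1000.0 * dt  # deg per sample
            k = np.arange(i1 - i0)
            x[i0:i1] = pos[0] + step * k * np.cos(theta)
            y[i0:i1] = pos[1] + step * k * np.sin(theta)
            moving[i0:i1] = True
            pos = np.array(
                [pos[0] + step * (i1 - i0) * np.cos(theta), pos[1] + step * (i1 - i0) * np.sin(theta)]
            )
            cursor = i1
    x[cursor:] = pos[0]
    y[cursor:] = pos[1]

    # blinks: invalidate the gap, add lid-artifact ramps on the flanks
    for b_start, b_dur in spec.blinks:
        g0 = int(round(b_start / dt))
        g1 = min(int(round((b_start + b_dur) / dt)), n)
        valid[g0:g1] = False
        amp = rng.uniform(0.04, 0.1) * dt  # deg per sample: 40-100 deg/s
        for j in range(BLINK_FLANK_SAMPLES):
            k = g0 - BLINK_FLANK_SAMPLES + j
            if 0 <= k < n:
                x[k] += (j + 1) * amp
            k = g1 + j
            if 0 <= k < n:
                x[k] += (BLINK_FLANK_SAMPLES - j) * amp
        # tracker junk inside the gap
        x[g0:g1] += (BLINK_FLANK_SAMPLES + 1) * amp

    if spec.fixation_noise_sd > 0:
        jitter = rng.normal(0.0, spec.fixation_noise_sd, size=(2, n))
        still = ~moving
        x[still] += jitter[0, still]
        y[still] += jitter[1, still]
    if spec.measurement_noise_sd > 0:
        x += rng.normal(0.0, spec.measurement_noise_sd, size=n)
        y += rng.normal(0.0, spec.measurement_noise_sd, size=n)

    trace = GazeTrace(t, x, y, valid, trace_id=f"synth-{spec.seed}")
    return trace, truth


# ---------------------------------------------------------------------------
# synthetic clips
# ---------------------------------------------------------------------------

MIN_CUT_CONTRAST = 40.0  # gray levels


def make_clip(
    n_frames: int,
    cut_frames: list[int] | None = None,
    fade_spans: list[tuple[int, int]] | None = None,
    base_levels: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (32, 32),
    frame_rate: float = 30.0,
    clip_id: str = "synth-clip",
) -> tuple[ClipFrames, GroundTruth]:
    """Uniform-intensity frames with abrupt cuts and/or linear fades.

    ``cut_frames[i]`` is the first frame of a new scene. Transitions (cuts and
    fades, ordered by position) step through ``base_levels`` sequentially, so
    ``len(base_levels)`` must be ``len(cuts) + len(fades) + 1``; consecutive
    levels across a cut must differ by at least 40 gray levels. Fades ramp
    linearly over ``(start, length)``. Pixel noise is i.i.d. Gaussian, clipped
    to [0, 255].
    """
    cut_frames = list(cut_frames or [])
    fade_spans = list(fade_spans or [])
    n_transitions = len(cut_frames) + len(fade_spans)
    if base_levels is None:
        base_levels = [60.0 + 60.0 * (i % 3) for i in range(n_transitions + 1)]
    if len(base_levels) != n_transitions + 1:
        raise SpecError(
            f"need {n_transitions + 1} base levels for {n_transitions} transitions, got {len(base_levels)}"
        )
    if any(c0 >= c1 for c0, c1 in zip(cut_frames, cut_frames[1:])):
        raise SpecError("cut frames must be strictly increasing")
    if any(not 0 < c < n_frames for c in cut_frames):
        raise SpecError("cut frames must lie strictly inside the clip")

    transitions = [(c, c, "cut") for c in cut_frames] + [
        (s, s + ln, "fade") for s, ln in fade_spans
    ]
    transitions.sort()
    for (a0, a1, _), (b0, b1, _) in zip(transitions, transitions[1:]):
        if b0 <= a1:
            raise SpecError("overlapping or touching cut/fade transitions")
    if transitions and (transitions[0][0] < 1 or transitions[-1][1] > n_frames - 1):
        raise SpecError("transitions must leave at least one plain frame at each end")

    level = np.full(n_frames, base_levels[0])
    for idx, (t0, t1, kind) in enumerate(transitions):
        nxt = base_levels[idx + 1]
        if kind == "cut":
            prev = level[t0 - 1]
            if abs(nxt - prev) < MIN_CUT_CONTRAST:
                raise SpecError(
                    f"cut at frame {t0}: contrast {abs(nxt - prev):.1f} below {MIN_CUT_CONTRAST}"
                )
            level[t0:] = nxt
        else:
            prev = level[t0 - 1]
            span = t1 - t0 + 1
            ramp = prev + (nxt - prev) * (np.arange(1, span + 1) / span)
            level[t0:t1 + 1] = ramp[: max(0, min(t1 + 1, n_frames) - t0)]
            level[t1 + 1:] = nxt

    rng = np.random.default_rng(seed)
    frames = np.broadcast_to(level[:, None, None], (n_frames, *shape)).astype(float).copy()
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, 255.0)
    truth = GroundTruth(cut_frames=cut_frames, fade_spans=fade_spans)
    return ClipFrames(frames, frame_rate=frame_rate, clip_id=clip_id), truth


# ---------------------------------------------------------------------------
# study-like default sessions
# ---------------------------------------------------------------------------


def standard_session_spec(
    n_saccades: int = 100,
    seed: int = 0,
    measurement_noise_sd: float = 0.02,
    fixation_noise_sd: float = 0.005,
    with_blinks: bool = True,
    with_pursuit: bool = True,
    sampling_rate: float = 1000.0,
) -> SessionSpec:
    """A session with the statistical structure of natural video viewing.

    Magnitudes are log-normal with median ~4 deg (clipped to 1.5-20 deg),
    durations follow a linear main-sequence rule (~21 ms + 2.2 ms/deg, kept
    within 16-99 ms), shape p3 is uniform on [1.5, 2.5], directions are
    uniform with half the saccades given a bow of up to 0.5 deg, and
    inter-saccade fixations last 150-400 ms. Blinks (~300 ms) and one slow
    pursuit segment (8 deg/s) are inserted in fixation periods when requested.
    """
    rng = np.random.default_rng(seed)
    saccades: list[SaccadeSpec] = []
    t_cursor = 250.0
    for i in range(n_saccades):
        mag = float(np.clip(rng.lognormal(mean=np.log(4.0), sigma=0.45), 1.5, 20.0))
        p3 = float(rng.uniform(1.5, 2.5))
        dur = float(np.clip(21.0 + 2.2 * mag, 16.0, 99.0))
        p2 = dur / (-np.log(1.0 - model.COMPLETION_FRACTION)) ** (1.0 / p3)
        direction = float(rng.uniform(0.0, 360.0))
        bow = float(rng.uniform(0.05, 0.5)) if rng.random() < 0.5 else 0.0
        saccades.append(
            SaccadeSpec(
                onset_ms=t_cursor,
                magnitude=mag,
                direction=direction,
                p2=p2,
                p3=p3,
                bow_amplitude=bow,
            )
        )
        t_cursor += model.duration_ms(p2, p3) + float(rng.uniform(150.0, 400.0))

    blinks: list[tuple[float, float]] = []
    pursuits: list[tuple[float, float, float, float]] = []
    gaps = []
    for a, b in zip(saccades, saccades[1:]):
        g0 = a.onset_ms + a.duration_ms + 25.0
        g1 = b.onset_ms - 25.0
        if g1 - g0 > 120.0:
            gaps.append((g0, g1))
    if with_blinks and len(gaps) >= 4:
        for frac in (0.25, 0.75):
            g0, g1 = gaps[int(frac * len(gaps))]
            dur = min(300.0, (g1 - g0) - 20.0)
            blinks.append((g0 + 10.0, dur))
    if with_pursuit and gaps:
        g0, g1 = gaps[len(gaps) // 2]
        if not any(abs(g0 - b0) < 1.0 for b0, _ in blinks):
            dur = min(200.0, (g1 - g0) - 20.0)
            pursuits.append((g0 + 10.0, dur, 8.0, float(rng.uniform(0, 360.0))))

    duration = t_cursor + 250.0
    return SessionSpec(
        duration_ms=duration,
        sampling_rate=sampling_rate,
        saccades=saccades,
        fixation_noise_sd=fixation_noise_sd,
        measurement_noise_sd=measurement_noise_sd,
        blinks=blinks,
        pursuits=pursuits,
        seed=seed,
    )
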