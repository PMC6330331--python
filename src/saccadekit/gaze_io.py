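"""I/O for every format the pipeline touches.

Containers
----------
:class:`GazeTrace`      uniformly sampled eye position with validity flags
:class:`ClipFrames`     an ordered stack of grayscale video frames
:class:`ClipCovariates` per-clip content ratings

Formats
-------
* gaze CSV           header ``t_ms,x_deg,y_deg,valid``; comma separator, ``.``
                     decimal, UTF-8 (bit-exact interchange)
* EyeLink ASC subset sample lines ``<t> <x> <y> <pupil>`` with ``.`` for
                     missing; events/messages are not parsed
* saccade event CSV  one row per saccade, full float precision, lossless
* scene-cut CSV      ``clip_id,frame_index,time_ms,metric``
* covariates CSV     one row per clip, eight rating columns
* frame directories  lexicographically ordered PNG/PGM images

Conventions: x positive rightward and y positive UPWARD in all internal math;
screen-style y-down sources are flipped at read time (``y_down=True``).
Direction angles are measured counterclockwise from rightward, in [0, 360).
Color frames are reduced to grayscale with ITU-R BT.601 luma weights
(0.299, 0.587, 0.114), rounded half-up.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ParseError

__all__ = [
    "GazeTrace",
    "ClipFrames",
    "ClipCovariates",
    "read_gaze",
    "write_gaze",
    "read_saccade_table",
    "write_saccade_table",
    "read_frames",
    "write_frames",
    "read_covariates",
    "write_covariates",
    "read_cut_table",
    "write_cut_table",
]

#: ITU-R BT.601 luma weights used for RGB -> grayscale reduction.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

GENRES = ("drama", "comedy", "action", "documentary", "animation")

#: Relative tolerance on the uniformity of the sampling step.
STEP_RTOL = 1e-9


@dataclass
class GazeTrace:
    """A uniformly sampled eye-position time series.

    ``sample_times`` are in ms and strictly increasing with a constant step
    (1 ms at the nominal 1 kHz); ``x_pos``/``y_pos`` are in degrees of visual
    angle (x rightward, y upward); ``valid`` is False where the tracker
    reported the sample missing (blinks). ``session_offset`` locates the trace
    within a longer session, in ms.
    """

    sample_times: np.ndarray
    x_pos: np.ndarray
    y_pos: np.ndarray
    valid: np.ndarray
    trace_id: str = ""
    session_offset: float = 0.0
    sampling_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.x_pos = np.asarray(self.x_pos, dtype=float)
        self.y_pos = np.asarray(self.y_pos, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.sample_times)
        if not (len(self.x_pos) == len(self.y_pos) == len(self.valid) == n):
            raise FormatError("GazeTrace arrays must have equal lengths")
        if n < 2:
            raise InsufficientDataError("GazeTrace needs at least 2 samples")
        steps = np.diff(self.sample_times)
        if np.any(steps <= 0):
            raise FormatError("sample_times must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > STEP_RTOL * max(abs(step), 1.0)):
            raise FormatError("sampling step is not uniform within tolerance")
        self.sampling_rate = 1000.0 / step

    def __len__(self) -> int:
        return len(self.sample_times)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            self.sample_times.copy(),
            self.x_pos.copy(),
            self.y_pos.copy(),
            self.valid.copy(),
            trace_id=self.trace_id,
            session_offset=self.session_offset,
        )


@dataclass
class ClipFrames:
    """An ordered stack of grayscale frames, values in [0, 255]."""

    frames: np.ndarray  # (n_frames, height, width) float64
    frame_rate: float
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be a (n, h, w) stack of equal-size matrices")
        if self.frames.shape[0] < 2:
            raise InsufficientDataError("a clip needs at least 2 frames")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise FormatError("frame intensities must lie in [0, 255]")
        if self.frame_rate <= 0:
            raise FormatError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ClipCovariates:
    """Content ratings for one clip: five 0-5 importance scales plus lighting,
    indoor/outdoor environment and genre."""

    clip_id: str
    faces: float
    human_figures: float
    man_made: float
    nature: float
    auditory: float
    lighting: int
    environment: str  # "indoor" | "outdoor"
    genre: str

    def __post_init__(self) -> None:
        for name in ("faces", "human_figures", "man_made", "nature", "auditory"):
            v = getattr(self, name)
            if not 0 <= v <= 5:
                raise FormatError(f"{name} rating {v} outside 0-5")
        if self.environment not in ("indoor", "outdoor"):
            raise FormatError(f"environment must be indoor/outdoor, got {self.environment!r}")
        if self.genre not in GENRES:
            raise FormatError(f"genre {self.genre!r} not one of {GENRES}")


# ---------------------------------------------------------------------------
# gaze traces
# ---------------------------------------------------------------------------

GAZE_HEADER = ["t_ms", "x_deg", "y_deg", "valid"]


def read_gaze(
    path: str | Path,
    dialect: str = "csv",
    y_down: bool = False,
    trace_id: str | None = None,
) -> GazeTrace:
    """Read a gaze trace from ``path``.

    ``dialect="csv"`` expects the header ``t_ms,x_deg,y_deg,valid``;
    ``dialect="eyelink_asc_subset"`` accepts raw sample lines
    ``<t> <x> <y> <pupil>`` with ``.`` marking missing data. ``y_down=True``
    flips the vertical axis so that internally y is positive upward.
    Positions of invalid samples are carried through as NaN placeholders.
    """
    path = Path(path)
    if dialect == "csv":
        t, x, y, v = _read_gaze_csv(path)
    elif dialect == "eyelink_asc_subset":
        t, x, y, v = _read_gaze_asc(path)
    else:
        raise FormatError(f"unknown gaze dialect {dialect!r}")
    if y_down:
        y = -y
    return GazeTrace(t, x, y, v, trace_id=trace_id if trace_id is not None else path.stem)


def _read_gaze_csv(path: Path):
    t, x, y, v = [], [], [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip() for h in header] != GAZE_HEADER:
            raise ParseError(f"{path}: line 1: expected header {','.join(GAZE_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(row)}")
            try:
                valid = row[3].strip() in ("1", "true", "True")
                t.append(float(row[0]))
                if valid:
                    x.append(float(row[1]))
                    y.append(float(row[2]))
                else:
                    x.append(_float_or_nan(row[1]))
                    y.append(_float_or_nan(row[2]))
                v.append(valid)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return (np.array(t), np.array(x), np.array(y), np.array(v, dtype=bool))


def _float_or_nan(token: str) -> float:
    token = token.strip()
    if token in ("", ".", "nan", "NaN"):
        return math.nan
    return float(token)


def _read_gaze_asc(path: Path):
    t, x, y, v = [], [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if not _is_number(parts[0]):
                continue  # event/message line: outside the sample subset
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected '<t> <x> <y> <pupil>'")
            try:
                ts = float(parts[0])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            missing = parts[1] == "." or parts[2] == "."
            t.append(ts)
            x.append(math.nan if missing else float(parts[1]))
            y.append(math.nan if missing else float(parts[2]))
            v.append(not missing)
    if not t:
        raise ParseError(f"{path}: no sample lines found")
    return (np.array(t), np.array(x), np.array(y), np.array(v, dtype=bool))


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_gaze(trace: GazeTrace, path: str | Path, y_down: bool = False) -> None:
    """Write a gaze trace as CSV (full float precision, lossless round-trip)."""
    y = -trace.y_pos if y_down else trace.y_pos
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(GAZE_HEADER)
        for i in range(len(trace)):
            writer.writerow(
                [
                    repr(float(trace.sample_times[i])),
                    repr(float(trace.x_pos[i])),
                    repr(float(y[i])),
                    int(trace.valid[i]),
                ]
            )


# ---------------------------------------------------------------------------
# saccade event tables
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "trace_id",
    "subject_id",
    "clip_id",
    "onset_ms",
    "offset_ms",
    "duration_ms",
    "magnitude_deg",
    "path_length_deg",
    "peak_velocity_deg_ms",
    "direction_deg",
    "orientation",
    "leftward",
    "downward",
    "session_offset_ms",
    "curvature",
    "p1",
    "p2",
    "p3",
    "deviation_deg_ms",
    "fit_converged",
    "inflight_cut",
    "rejection_reason",
]


def write_saccade_table(events: Sequence, path: str | Path) -> None:
    """Write saccade events as CSV with the documented column order.

    Floats are written at full precision so a read-back is lossless. An empty
    event list produces a header-only file.
    """
    rows = []
    for ev in events:
        fit = ev.profile_fit
        rows.append(
            {
                "trace_id": ev.trace_id,
                "subject_id": "" if ev.subject_id is None else ev.subject_id,
                "clip_id": "" if ev.clip_id is None else ev.clip_id,
                "onset_ms": ev.onset_ms,
                "offset_ms": ev.offset_ms,
                "duration_ms": ev.duration_ms,
                "magnitude_deg": ev.magnitude_deg,
                "path_length_deg": ev.path_length_deg,
                "peak_velocity_deg_ms": ev.peak_velocity_deg_ms,
                "direction_deg": ev.direction_deg,
                "orientation": ev.orientation,
                "leftward": int(ev.leftward),
                "downward": int(ev.downward),
                "session_offset_ms": ev.session_offset_ms,
                "curvature": "" if ev.curvature is None else repr(float(ev.curvature)),
                "p1": "" if fit is None else repr(float(fit.p1)),
                "p2": "" if fit is None else repr(float(fit.p2)),
                "p3": "" if fit is None else repr(float(fit.p3)),
                "deviation_deg_ms": "" if fit is None else repr(float(fit.deviation)),
                "fit_converged": "" if fit is None else int(fit.converged),
                "inflight_cut": int(ev.inflight_cut),
                "rejection_reason": "" if ev.rejection_reason is None else ev.rejection_reason,
            }
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=EVENT_COLUMNS)
        writer.writeheader()
        for row in rows:
            for key, val in row.items():
                if isinstance(val, float):
                    row[key] = repr(val)
            writer.writerow(row)


def read_saccade_table(path: str | Path) -> list:
    """Read a saccade event CSV written by :func:`write_saccade_table`."""
    from .detect import SaccadeEvent
    from .metrics import VelocityProfileFit

    events = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != EVENT_COLUMNS:
            raise ParseError(f"{path}: unexpected saccade-table header")
        for lineno, row in enumerate(reader, start=2):
            try:
                fit = None
                if row["p1"] != "":
                    fit = VelocityProfileFit(
                        p1=float(row["p1"]),
                        p2=float(row["p2"]),
                        p3=float(row["p3"]),
                        deviation=float(row["deviation_deg_ms"]),
                        converged=bool(int(row["fit_converged"])),
                        n_samples=0,
                    )
                events.append(
                    SaccadeEvent(
                        onset_ms=float(row["onset_ms"]),
                        offset_ms=float(row["offset_ms"]),
                        magnitude_deg=float(row["magnitude_deg"]),
                        path_length_deg=float(row["path_length_deg"]),
                        peak_velocity_deg_ms=float(row["peak_velocity_deg_ms"]),
                        direction_deg=float(row["direction_deg"]),
                        orientation=row["orientation"],
                        leftward=bool(int(row["leftward"])),
                        downward=bool(int(row["downward"])),
                        trace_id=row["trace_id"],
                        subject_id=row["subject_id"] or None,
                        clip_id=row["clip_id"] or None,
                        session_offset_ms=float(row["session_offset_ms"]),
                        curvature=float(row["curvature"]) if row["curvature"] != "" else None,
                        profile_fit=fit,
                        inflight_cut=bool(int(row["inflight_cut"])),
                        rejection_reason=row["rejection_reason"] or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return events


# ---------------------------------------------------------------------------
# video frames
# ---------------------------------------------------------------------------

FRAME_SUFFIXES = (".png", ".pgm", ".bmp", ".tif", ".tiff")


def read_frames(dir_path: str | Path, frame_rate: float = 30.0, clip_id: str | None = None) -> ClipFrames:
    """Read a lexicographically ordered directory of images as grayscale frames.

    Color images are reduced with BT.601 luma weights and rounded half-up to
    integers so the result is identical to what a grayscale export would hold.
    """
    dir_path = Path(dir_path)
    files = sorted(p for p in dir_path.iterdir() if p.suffix.lower() in FRAME_SUFFIXES)
    if len(files) < 2:
        raise InsufficientDataError(f"{dir_path}: need at least 2 frame images, found {len(files)}")
    frames = []
    shape = None
    for p in files:
        arr = np.asarray(iio.imread(p))
        gray = to_grayscale(arr)
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise FormatError(f"{p}: frame shape {gray.shape} differs from {shape}")
        frames.append(gray)
    return ClipFrames(np.stack(frames), frame_rate=frame_rate, clip_id=clip_id or dir_path.name)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """BT.601 grayscale reduction, rounded half-up; pass-through for 2-D input."""
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(float)
        luma = rgb @ np.array(LUMA_WEIGHTS)
        return np.floor(luma + 0.5)
    raise FormatError(f"unsupported image shape {arr.shape}")


def write_frames(clip: ClipFrames, dir_path: str | Path) -> list[Path]:
    """Write frames as zero-padded PNG files (frame_00000.png, ...)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(clip.frames):
        p = dir_path / f"frame_{i:05d}.png"
        iio.imwrite(p, np.clip(np.round(frame), 0, 255).astype(np.uint8))
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# covariates and cut tables
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = [
    "clip_id",
    "faces",
    "human_figures",
    "man_made",
    "nature",
    "auditory",
    "lighting",
    "environment",
    "genre",
]


def write_covariates(covs: Iterable[ClipCovariates], path: str | Path) -> None:
    rows = [
        {
            "clip_id": c.clip_id,
            "faces": c.faces,
            "human_figures": c.human_figures,
            "man_made": c.man_made,
            "nature": c.nature,
            "auditory": c.auditory,
            "lighting": c.lighting,
            "environment": c.environment,
            "genre": c.genre,
        }
        for c in covs
    ]
    pd.DataFrame(rows, columns=COVARIATE_COLUMNS).to_csv(path, index=False)


def read_covariates(path: str | Path) -> list[ClipCovariates]:
    df = pd.read_csv(path, dtype={"clip_id": str})
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing covariate columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ClipCovariates(
                    clip_id=str(row["clip_id"]),
                    faces=float(row["faces"]),
                    human_figures=float(row["human_figures"]),
                    man_made=float(row["man_made"]),
                    nature=float(row["nature"]),
                    auditory=float(row["auditory"]),
                    lighting=int(row["lighting"]),
                    environment=str(row["environment"]),
                    genre=str(row["genre"]),
                )
            )
        except (ValueError, FormatError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from None
    return out


CUT_COLUMNS = ["clip_id", "frame_index", "time_ms", "metric"]


def write_cut_table(clip_id: str, cutset, path: str | Path) -> None:
    """Write accepted scene cuts as ``clip_id,frame_index,time_ms,metric``."""
    rows = []
    for frame, t in zip(cutset.cut_frames, cutset.cut_times_ms):
        rows.append(
            {
                "clip_id": clip_id,
                "frame_index": int(frame),
                "time_ms": float(t),
                "metric": float(cutset.metric[frame - 1]),
            }
        )
    pd.DataFrame(rows, columns=CUT_COLUMNS).to_csv(path, index=False)


def read_cut_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CUT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing cut-table columns {sorted(missing)}")
    return df
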