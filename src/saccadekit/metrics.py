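"""Per-saccade outcome measures: trajectory curvature and velocity-profile deviation.

Curvature
---------
The pointwise curvature of a sampled path (x_t, y_t), t = 1..T, is the norm of
the discrete second difference normalized by the total path length:

    k_t = ||p_{t+1} - 2 p_t + p_{t-1}|| / sum_t ||p_t - p_{t-1}||,   t = 2..T-1

and the saccade's curvature k is the MEDIAN of the k_t. The measure is
dimensionless and invariant under rotation, translation and uniform scaling.
Because the second difference also contains tangential (along-track)
acceleration, a straight path traversed at varying speed has k_t > 0 under
this definition; the ``perpendicular`` variant replaces the numerator by the
component of the second difference orthogonal to the local tangent, which is
zero on any straight path regardless of speed profile. The literal
``as_written`` form is the default.

Velocity-profile deviation
--------------------------
The along-track displacement of a saccade is fit with the compressed
exponential model f(t) = p1[1 - exp(-(t/p2)^p3)] (see :mod:`saccadekit.model`)
by bounded nonlinear least squares in the position domain. The deviation score
is the root-mean-square discrepancy, in deg/ms, between the measured speed and
the model's velocity profile over the event samples. By default the model
velocity is obtained by applying the same discrete derivative operator used
for the measured speed to the fitted displacement curve (so a noiseless
model-generated saccade scores ~0); the closed-form derivative is available
with ``velocity_residual="analytic"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

from . import model
from .errors import DegeneratePathError, InsufficientDataError
from .preprocess import SpeedTrace

if TYPE_CHECKING:  # pragma: no cover
    from .detect import SaccadeEvent

__all__ = [
    "CurvatureResult",
    "VelocityProfileFit",
    "pointwise_curvature",
    "fit_displacement_series",
    "fit_profile",
    "attach_metrics",
]


@dataclass
class CurvatureResult:
    """Pointwise curvature series k_t (t = 2..T-1) and its median k."""

    pointwise: np.ndarray
    k: float


@dataclass
class VelocityProfileFit:
    """Fitted compressed-exponential parameters and the deviation score.

    p1: amplitude (deg); p2: time scale (ms); p3: shape (dimensionless);
    deviation: RMS velocity error (deg/ms). ``converged=False`` means the
    optimizer exhausted its iteration budget; the deviation is still reported.
    """

    p1: float
    p2: float
    p3: float
    deviation: float
    converged: bool
    n_samples: int


def pointwise_curvature(x, y, variant: str = "as_written") -> CurvatureResult:
    """Median pointwise curvature of the sampled path (x, y).

    Requires >= 4 samples and a path of positive length. ``variant`` selects
    the numerator: ``as_written`` (norm of the second difference) or
    ``perpendicular`` (its component orthogonal to the local tangent
    p_{t+1} - p_{t-1}).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegeneratePathError("x and y must be 1-D arrays of equal length")
    T = len(x)
    if T < 4:
        raise InsufficientDataError(f"curvature needs >= 4 samples, got {T}")
    dx = np.diff(x)
    dy = np.diff(y)
    path_length = float(np.sum(np.hypot(dx, dy)))
    if path_length == 0.0:
        raise DegeneratePathError("zero path length")
    ddx = np.diff(dx)  # second differences at t = 2..T-1
    ddy = np.diff(dy)
    if variant == "as_written":
        num = np.hypot(ddx, ddy)
    elif variant == "perpendicular":
        # tangent at interior sample t: central difference p_{t+1} - p_{t-1}
        tx = x[2:] - x[:-2]
        ty = y[2:] - y[:-2]
        norm = np.hypot(tx, ty)
        num = np.empty_like(ddx)
        nz = norm > 0
        num[nz] = np.abs(tx[nz] * ddy[nz] - ty[nz] * ddx[nz]) / norm[nz]
        num[~nz] = np.hypot(ddx[~nz], ddy[~nz])  # stationary point: no tangent
    else:
        raise ValueError(f"unknown curvature variant {variant!r}")
    kt = num / path_length
    return CurvatureResult(pointwise=kt, k=float(np.median(kt)))


def _fit_displacement(d: np.ndarray, t: np.ndarray, magnitude: float, duration: float,
                      max_iter: int, tol: float):
    """Bounded least squares of the compressed exponential to displacement d(t)."""
    p0 = np.array([max(magnitude, 1e-6), max(duration / 2.0, 1e-3), 2.0])
    lo = np.array([1e-9, 1e-9, 0.5])
    hi = np.array([3.0 * max(magnitude, 1e-6), 3.0 * max(duration, 1e-3), 10.0])
    p0 = np.clip(p0, lo, hi)

    def residuals(p):
        return model.displacement(t, *p) - d

    res = least_squares(
        residuals,
        p0,
        bounds=(lo, hi),
        method="trf",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 4,
    )
    return res.x, bool(res.status > 0)


def fit_displacement_series(
    d,
    t,
    init_magnitude: float | None = None,
    init_duration: float | None = None,
    max_iterations: int = 200,
    tolerance: float = 1e-10,
) -> tuple[float, float, float, bool]:
    """Fit the compressed exponential to a bare displacement series.

    ``d`` (deg) and ``t`` (ms, from onset) must be equal-length 1-D arrays.
    Initialization defaults to p1 = final displacement, p2 = half the span,
    p3 = 2. Returns (p1, p2, p3, converged).
    """
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    if d.shape != t.shape or d.ndim != 1:
        raise InsufficientDataError("d and t must be 1-D arrays of equal length")
    if len(d) < 8:
        raise InsufficientDataError(f"profile fit needs >= 8 samples, got {len(d)}")
    mag = float(d[-1]) if init_magnitude is None else float(init_magnitude)
    dur = float(t[-1] - t[0]) if init_duration is None else float(init_duration)
    params, converged = _fit_displacement(d, t, mag, dur, max_iterations, tolerance)
    return float(params[0]), float(params[1]), float(params[2]), converged


def fit_profile(
    event: "SaccadeEvent",
    speed: SpeedTrace,
    velocity_residual: str = "discrete",
    displacement_mode: str = "from_start",
    max_iterations: int = 200,
    tolerance: float = 1e-10,
) -> VelocityProfileFit:
    """Fit the compressed exponential to one detected saccade.

    The displacement series is the Euclidean distance of each event sample
    from the onset-sample position (``displacement_mode="cumulative"``
    substitutes cumulative path length), with time measured from onset in ms.
    Initialization: p1 = event magnitude, p2 = duration/2, p3 = 2; bounds
    p1 in (0, 3*magnitude], p2 in (0, 3*duration], p3 in [0.5, 10].
    """
    i0, i1 = event.onset_idx, event.offset_idx
    sl = slice(i0, i1 + 1)
    x = speed.smoothed_x[sl]
    y = speed.smoothed_y[sl]
    n = len(x)
    if n < 8:
        raise InsufficientDataError(f"profile fit needs >= 8 samples, got {n}")
    t = speed.sample_times[sl] - speed.sample_times[i0]
    if displacement_mode == "cumulative":
        steps = np.hypot(np.diff(x), np.diff(y))
        d = np.concatenate([[0.0], np.cumsum(steps)])
    else:
        d = np.hypot(x - x[0], y - y[0])
    params, converged = _fit_displacement(
        d, t, magnitude=event.magnitude_deg, duration=event.duration_ms,
        max_iter=max_iterations, tol=tolerance,
    )
    p1, p2, p3 = (float(v) for v in params)
    measured = speed.speed[sl]
    if velocity_residual == "analytic":
        modeled = model.velocity(t, p1, p2, p3)
    else:
        # same central-difference operator as the measured speed, including at
        # the event edges: displacement is identically 0 before onset and the
        # model curve continues past the offset sample
        dt = t[1] - t[0]
        t_ext = np.concatenate([[t[0] - dt], t, [t[-1] + dt]])
        f_ext = np.where(
            t_ext <= 0.0, 0.0, model.displacement(np.maximum(t_ext, 0.0), p1, p2, p3)
        )
        modeled = np.gradient(f_ext, t_ext)[1:-1]
    deviation = float(np.sqrt(np.mean((measured - modeled) ** 2)))
    return VelocityProfileFit(p1=p1, p2=p2, p3=p3, deviation=deviation,
                              converged=converged, n_samples=n)


def attach_metrics(events, speed: SpeedTrace, config=None):
    """Fill ``curvature`` and ``profile_fit`` on each accepted event in place.

    Events too short for the profile fit keep ``profile_fit=None``. Returns
    the same list for chaining.
    """
    from .config import RunConfig

    config = config or RunConfig()
    for ev in events:
        sl = slice(ev.onset_idx, ev.offset_idx + 1)
        try:
            ev.curvature = pointwise_curvature(
                speed.smoothed_x[sl], speed.smoothed_y[sl], variant=config.curvature_variant
            ).k
        except (InsufficientDataError, DegeneratePathError):
            ev.curvature = None
        try:
            ev.profile_fit = fit_profile(
                ev,
                speed,
                velocity_residual=config.velocity_residual,
                displacement_mode=config.displacement_mode,
                max_iterations=config.fit_max_iterations,
                tolerance=config.fit_tolerance,
            )
        except InsufficientDataError:
            ev.profile_fit = None
    return events
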