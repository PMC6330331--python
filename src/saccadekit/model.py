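"""Compressed (generalized) exponential saccade model.

A saccade's along-track displacement is modelled as a saturating curve

    f(t) = p1 * (1 - exp(-(t / p2) ** p3))

with amplitude ``p1`` (degrees), time scale ``p2`` (ms) and shape ``p3``
(dimensionless). ``p3 = 1`` reduces to the standard exponential saturation;
``p3 > 1`` produces the slower-deceleration-than-acceleration velocity profile
characteristic of real saccades. The model velocity is the time derivative

    f'(t) = p1 * p3 / p2 * (t / p2) ** (p3 - 1) * exp(-(t / p2) ** p3)

in degrees/ms when ``t`` and ``p2`` are in ms.

The model is asymptotic, so a finite event duration is defined operationally as
the time at which ``f`` reaches a fixed fraction (default 99.9%) of ``p1``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "displacement",
    "velocity",
    "duration_ms",
    "peak_velocity",
]

#: Fraction of the asymptotic amplitude at which a saccade is considered over.
COMPLETION_FRACTION = 0.999


def displacement(t, p1: float, p2: float, p3: float):
    """Along-track displacement f(t), degrees. ``t`` in ms, scalar or array, t >= 0."""
    t = np.asarray(t, dtype=float)
    return p1 * (1.0 - np.exp(-((t / p2) ** p3)))


def velocity(t, p1: float, p2: float, p3: float):
    """Model speed f'(t) in degrees/ms.

    At ``t = 0`` the analytic limit is 0 for ``p3 > 1``, ``p1/p2`` for
    ``p3 = 1`` and diverges for ``p3 < 1``; the divergent case is clamped to
    the value one hundredth of a millisecond in, keeping downstream
    root-mean-square residuals finite.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t).copy()
    zero = t <= 0.0
    if p3 < 1.0:
        t[zero] = 1e-2
        u = t / p2
        out = p1 * p3 / p2 * u ** (p3 - 1.0) * np.exp(-(u**p3))
    else:
        t[zero] = 1.0  # placeholder, overwritten below
        u = t / p2
        out = p1 * p3 / p2 * u ** (p3 - 1.0) * np.exp(-(u**p3))
        out[zero] = p1 / p2 if p3 == 1.0 else 0.0
    return out[0] if scalar else out


def duration_ms(p2: float, p3: float, fraction: float = COMPLETION_FRACTION) -> float:
    """Operational saccade duration: time at which f(t) = fraction * p1."""
    return p2 * (-np.log(1.0 - fraction)) ** (1.0 / p3)


def peak_velocity(p1: float, p2: float, p3: float) -> float:
    """Analytic maximum of f'(t).

    For ``p3 > 1`` the maximum is at ``(t/p2)**p3 = (p3-1)/p3``; for
    ``p3 <= 1`` the profile is monotone decreasing and the peak sits at the
    clamped origin (see :func:`velocity`).
    """
    if p3 <= 1.0:
        return float(velocity(0.0, p1, p2, p3))
    u_pow = (p3 - 1.0) / p3
    t_peak = p2 * u_pow ** (1.0 / p3)
    return float(velocity(t_peak, p1, p2, p3))
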