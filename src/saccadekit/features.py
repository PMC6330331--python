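"""Saccade-level analysis table and univariable log-log cubic fits.

Each accepted saccade becomes one row with base-10 log transforms of the three
outcome measures (curvature, velocity-profile deviation, duration) plus their
exact squares and cubes, one-hot orientation dummies, direction flags, the
in-flight-cut indicator, a 30-s time-on-task bin, and joined clip/subject
covariates. Content ratings are recoded low (<= 1) / medium (2-3) / high
(>= 4). The table is ready for a crossed-random mixed-effects fit in any
established solver (subject and clip as crossed random factors); the fitting
itself is deliberately out of this module's scope — its bespoke content is the
measures and codings, not the solver.

Univariable relationships between the log outcomes are summarized with
ordinary-least-squares cubic polynomials y ~ 1 + x + x^2 + x^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePredictorError, InsufficientDataError, JoinError
from .gaze_io import ClipCovariates

__all__ = ["CubicFit", "build_table", "fit_cubic", "export_model_table", "content_level"]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "subject_id",
    "clip_id",
    "log_k",
    "log_k2",
    "log_k3",
    "log_dev",
    "log_dev2",
    "log_dev3",
    "log_dur",
    "log_dur2",
    "log_dur3",
    "orientation_horizontal",
    "orientation_vertical",
    "orientation_oblique",
    "leftward",
    "downward",
    "inflight_cut",
    "time_on_task_bin",
    "faces_level",
    "human_figures_level",
    "man_made_level",
    "nature_level",
    "auditory_level",
    "lighting",
    "environment",
    "genre",
    "age",
    "gender",
    "education",
]

#: Reference categories for downstream dummy coding (documented, not enforced):
#: orientation=horizontal, direction=rightward/upward, genre=comedy.
REFERENCE_LEVELS = {"orientation": "horizontal", "genre": "comedy"}


def content_level(rating: float) -> str:
    """Recode a 0-5 content rating: low (<= 1), medium (2-3 band), high (>= 4)."""
    if not 0 <= rating <= 5:
        raise ValueError(f"rating {rating} outside [0, 5]")
    if rating <= 1:
        return "low"
    if rating >= 4:
        return "high"
    return "medium"


@dataclass
class CubicFit:
    """OLS cubic fit y ~ 1 + x + x^2 + x^3."""

    coefficients: np.ndarray  # b0..b3
    standard_errors: np.ndarray
    n: int
    r_squared: float
    residual_sd: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.coefficients @ np.vstack([np.ones_like(x), x, x**2, x**3])


def build_table(
    events: Sequence,
    clip_covariates: Sequence[ClipCovariates] | None = None,
    subject_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One analysis row per accepted saccade.

    Events must carry curvature and a profile fit with positive deviation and
    duration; rows with nonpositive curvature or deviation cannot be
    log-transformed and are dropped with a logged count. ``subject_covariates``
    is a DataFrame with columns subject_id, age (years), gender, education
    (ISCED level 1-7). A missing join key raises, naming the offending ids.
    """
    cov_by_clip = {c.clip_id: c for c in clip_covariates} if clip_covariates else {}
    subj_by_id = {}
    if subject_covariates is not None:
        subj_by_id = {str(r["subject_id"]): r for _, r in subject_covariates.iterrows()}

    missing_clips = sorted(
        {ev.clip_id for ev in events if ev.clip_id is not None and clip_covariates is not None}
        - set(cov_by_clip)
    )
    if missing_clips:
        raise JoinError(f"clip covariates missing for clip ids: {missing_clips}")
    missing_subj = sorted(
        {ev.subject_id for ev in events if ev.subject_id is not None and subject_covariates is not None}
        - set(subj_by_id)
    )
    if missing_subj:
        raise JoinError(f"subject covariates missing for subject ids: {missing_subj}")

    rows = []
    dropped = 0
    for ev in events:
        if ev.curvature is None or ev.profile_fit is None:
            dropped += 1
            continue
        k = ev.curvature
        dev = ev.profile_fit.deviation
        dur = ev.duration_ms
        if k <= 0 or dev <= 0 or dur <= 0:
            dropped += 1
            continue
        log_k = np.log10(k)
        log_dev = np.log10(dev)
        log_dur = np.log10(dur)
        row = {
            "subject_id": ev.subject_id,
            "clip_id": ev.clip_id,
            "log_k": log_k,
            "log_k2": log_k * log_k,
            "log_k3": log_k * log_k * log_k,
            "log_dev": log_dev,
            "log_dev2": log_dev * log_dev,
            "log_dev3": log_dev * log_dev * log_dev,
            "log_dur": log_dur,
            "log_dur2": log_dur * log_dur,
            "log_dur3": log_dur * log_dur * log_dur,
            "orientation_horizontal": int(ev.orientation == "horizontal"),
            "orientation_vertical": int(ev.orientation == "vertical"),
            "orientation_oblique": int(ev.orientation == "oblique"),
            "leftward": int(ev.leftward),
            "downward": int(ev.downward),
            "inflight_cut": int(ev.inflight_cut),
            "time_on_task_bin": 1 + int(ev.session_offset_ms // 30000),
        }
        cov = cov_by_clip.get(ev.clip_id)
        row["faces_level"] = content_level(cov.faces) if cov else None
        row["human_figures_level"] = content_level(cov.human_figures) if cov else None
        row["man_made_level"] = content_level(cov.man_made) if cov else None
        row["nature_level"] = content_level(cov.nature) if cov else None
        row["auditory_level"] = content_level(cov.auditory) if cov else None
        row["lighting"] = cov.lighting if cov else None
        row["environment"] = cov.environment if cov else None
        row["genre"] = cov.genre if cov else None
        subj = subj_by_id.get(ev.subject_id) if ev.subject_id is not None else None
        row["age"] = subj["age"] if subj is not None else None
        row["gender"] = subj["gender"] if subj is not None else None
        row["education"] = subj["education"] if subj is not None else None
        rows.append(row)
    if dropped:
        logger.info("build_table: dropped %d events with missing or nonpositive outcomes", dropped)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def fit_cubic(y, x) -> CubicFit:
    """OLS of y on (1, x, x^2, x^3) via the pseudoinverse; deterministic.

    Requires n >= 5 and at least 4 distinct x values (otherwise the Vandermonde
    design is rank deficient).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegeneratePredictorError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 5:
        raise InsufficientDataError(f"cubic fit needs n >= 5, got {n}")
    X = np.column_stack([np.ones(n), x, x**2, x**3])
    if np.linalg.matrix_rank(X) < 4:
        raise DegeneratePredictorError("cubic design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 4
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return CubicFit(
        coefficients=beta,
        standard_errors=se,
        n=n,
        r_squared=r2,
        residual_sd=float(np.sqrt(sigma2)),
    )


def export_model_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the analysis table as CSV after asserting polynomial consistency.

    The square/cube columns must equal exact powers of the base columns; this
    is re-checked on every export so a hand-edited table cannot silently
    corrupt a downstream mixed-effects fit.
    """
    for base in ("log_k", "log_dev", "log_dur"):
        if len(table):
            b = table[base].to_numpy()
            # plain multiplication: bit-identical whether computed on scalars
            # or arrays, unlike pow()
            if not np.array_equal(table[f"{base}2"].to_numpy(), b * b):
                raise AssertionError(f"{base}2 is not the exact square of {base}")
            if not np.array_equal(table[f"{base}3"].to_numpy(), b * b * b):
                raise AssertionError(f"{base}3 is not the exact cube of {base}")
    table.to_csv(path, index=False, float_format="%.17g")
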