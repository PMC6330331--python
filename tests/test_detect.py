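"""Saccade segmentation, inclusion rules, orientation, main sequence."""

import numpy as np
import pytest

import saccadekit as sk
from saccadekit.config import RunConfig
from saccadekit.detect import apply_filters, classify_orientation, main_sequence, segment
from saccadekit.errors import DegeneratePredictorError, InsufficientDataError
from saccadekit.preprocess import SpeedTrace

from conftest import match_events


def _speed_trace(speed, x=None, y=None):
    n = len(speed)
    return SpeedTrace(
        sample_times=np.arange(float(n)),
        speed=np.asarray(speed, dtype=float),
        smoothed_x=np.zeros(n) if x is None else np.asarray(x, dtype=float),
        smoothed_y=np.zeros(n) if y is None else np.asarray(y, dtype=float),
        interpolated_mask=np.zeros(n, dtype=bool),
    )


class TestSegment:
    def test_subthreshold_speed_gives_no_candidates(self):
        st = _speed_trace(np.full(100, 0.02))  # 20 deg/s everywhere
        assert segment(st) == []

    def test_rectangular_pulse_yields_one_candidate_of_matching_duration(self):
        speed = np.zeros(100)
        speed[40:53] = 0.1  # 13 samples above threshold: offset - onset = 12 ms
        x = np.concatenate([np.zeros(40), np.cumsum(np.full(13, 0.1)), np.full(47, 1.3)])
        st = _speed_trace(speed, x=x)
        events = segment(st)
        assert len(events) == 1
        assert events[0].duration_ms == 12.0
        assert events[0].onset_ms == 40.0

    def test_pulse_shorter_than_min_above_dropped(self):
        speed = np.zeros(100)
        speed[40:48] = 0.1  # 8 ms < 10 ms
        assert segment(_speed_trace(speed)) == []

    def test_low_noise_session_candidates_match_truth(self):
        spec = sk.standard_session_spec(n_saccades=20, seed=11, measurement_noise_sd=0.005,
                                        with_blinks=False, with_pursuit=False)
        trace, truth = sk.make_session(spec)
        speed = sk.preprocess_trace(trace)
        candidates = segment(speed)
        assert len(candidates) == 20
        errors = [min(abs(c.onset_ms - g.onset_ms) for g in truth.saccades) for c in candidates]
        assert max(errors) <= 3.0


class TestFilters:
    @staticmethod
    def _run_single(magnitude=5.0, n_samples=31, peak=0.5, initial=0.031,
                    terminal=0.031, quartile_frac=0.9):
        """Build one supra-threshold run with prescribed kinematic readings."""
        n = n_samples + 40
        speed = np.full(n, 0.001)
        i0, i1 = 20, 20 + n_samples - 1
        speed[i0 : i1 + 1] = 0.6 * peak  # supra-threshold body
        speed[i0] = initial
        speed[i1] = terminal
        speed[(i0 + i1) // 2] = peak
        qi = i0 + n_samples // 4
        speed[qi] = max(quartile_frac * peak, 0.031)
        x = np.zeros(n)
        x[i0 : i1 + 1] = np.linspace(0, magnitude, n_samples)
        x[i1 + 1 :] = magnitude
        st = _speed_trace(speed, x=x)
        candidates = segment(st)
        assert len(candidates) == 1
        return apply_filters(candidates, st)

    def test_well_formed_saccade_accepted(self):
        accepted, rejected = self._run_single()
        assert len(accepted) == 1 and not rejected

    @pytest.mark.parametrize(
        "kwargs, reason",
        [
            ({"magnitude": 0.5}, "magnitude_low"),
            ({"magnitude": 45.0}, "magnitude_high"),
            ({"n_samples": 15}, "duration_short"),
            ({"initial": 0.08}, "initial_velocity"),
            ({"terminal": 0.31}, "terminal_velocity"),
            ({"quartile_frac": 0.10}, "slow_first_quartile"),
        ],
    )
    def test_each_rule_rejects_with_its_reason(self, kwargs, reason):
        accepted, rejected = self._run_single(**kwargs)
        assert not accepted
        assert [ev.rejection_reason for ev in rejected] == [reason]

    def test_model_generated_saccade_passes_every_rule(self):
        spec = sk.SaccadeSpec(onset_ms=100, magnitude=5, direction=0, p2=12, p3=2)
        session = sk.SessionSpec(duration_ms=500, saccades=[spec])
        trace, _ = sk.make_session(session)
        speed = sk.preprocess_trace(trace)
        accepted, rejected = sk.detect_saccades(speed)
        assert len(accepted) == 1 and not rejected

    def test_boundary_touching_candidate_rejected(self):
        speed = np.full(40, 0.001)
        speed[0:20] = 0.2
        st = _speed_trace(speed)
        accepted, rejected = apply_filters(segment(st), st)
        assert not accepted
        assert rejected[0].rejection_reason == "boundary"

    def test_candidates_partition_into_accepted_and_rejected(self, reference_detection):
        speed, accepted, rejected, _ = reference_detection
        candidates = segment(speed)
        assert len(accepted) + len(rejected) == len(candidates)
        assert all(ev.rejection_reason is None for ev in accepted)
        assert all(ev.rejection_reason in sk.detect.REJECTION_REASONS for ev in rejected)


class TestOrientation:
    @pytest.mark.parametrize(
        "direction, orientation, leftward, downward",
        [
            (3, "horizontal", False, False),
            (5, "horizontal", False, False),
            (6, "oblique", False, False),
            (45, "oblique", False, False),
            (68, "vertical", False, False),
            (85, "vertical", False, False),
            (112, "vertical", True, False),
            (175, "horizontal", True, False),
            (185, "horizontal", True, True),
            (200, "oblique", True, True),
            (248, "vertical", True, True),
            (270, "vertical", False, True),
            (292, "vertical", False, True),
            (300, "oblique", False, True),
            (356, "horizontal", False, True),
            (0, "horizontal", False, False),
        ],
    )
    def test_taxonomy_bands_and_direction_flags(self, direction, orientation, leftward, downward):
        assert classify_orientation(direction) == (orientation, leftward, downward)


class TestMainSequence:
    def test_peak_velocity_monotone_in_magnitude_at_fixed_shape(self):
        events = []
        for mag in (2, 4, 8):
            spec = sk.SaccadeSpec(onset_ms=100, magnitude=mag, direction=0, p2=12, p3=2)
            trace, _ = sk.make_session(sk.SessionSpec(duration_ms=500, saccades=[spec]))
            speed = sk.preprocess_trace(trace)
            accepted, _ = sk.detect_saccades(speed)
            events.extend(accepted)
        pv = [ev.peak_velocity_deg_ms for ev in events]
        assert pv[0] < pv[1] < pv[2]

    def test_fit_matches_closed_form_ols_oracle(self, reference_detection):
        _, accepted, _, _ = reference_detection
        table, slope, intercept = main_sequence(accepted)
        lx = np.log10(table[:, 0])
        ly = np.log10(table[:, 2])
        # normal-equations oracle
        X = np.column_stack([np.ones_like(lx), lx])
        beta = np.linalg.solve(X.T @ X, X.T @ ly)
        assert slope == pytest.approx(beta[1], abs=1e-8)
        assert intercept == pytest.approx(beta[0], abs=1e-8)

    def test_degenerate_and_insufficient_inputs_raise(self):
        spec = sk.SaccadeSpec(onset_ms=100, magnitude=5, direction=0, p2=12, p3=2)
        trace, _ = sk.make_session(sk.SessionSpec(duration_ms=500, saccades=[spec]))
        speed = sk.preprocess_trace(trace)
        accepted, _ = sk.detect_saccades(speed)
        with pytest.raises(InsufficientDataError):
            main_sequence(accepted)  # only one event
        with pytest.raises(DegeneratePredictorError):
            main_sequence(accepted * 3)  # identical magnitudes


class TestRecallPrecision:
    def test_noise_free_detection_is_perfect(self, clean_session):
        _, trace, truth = clean_session
        speed = sk.preprocess_trace(trace)
        accepted, _ = sk.detect_saccades(speed)
        tp = match_events(accepted, truth)
        assert tp == len(truth.saccades) == len(accepted)
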