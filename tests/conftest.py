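"""Shared fixtures: seeded synthetic sessions and event-matching helpers."""

import numpy as np
import pytest

import saccadekit as sk


def match_events(accepted, truth, return_errors=False):
    """Greedy one-to-one matching of detected events to ground-truth saccades
    by interval overlap; returns the true-positive count (and onset errors)."""
    used = set()
    tp = 0
    errors = []
    for ev in accepted:
        best, best_d = None, np.inf
        for i, g in enumerate(truth.saccades):
            if i in used:
                continue
            if ev.onset_ms <= g.offset_ms and g.onset_ms <= ev.offset_ms:
                d = abs(ev.onset_ms - g.onset_ms)
                if d < best_d:
                    best, best_d = i, d
        if best is not None:
            used.add(best)
            tp += 1
            errors.append(best_d)
    return (tp, errors) if return_errors else tp


@pytest.fixture(scope="session")
def reference_session():
    """The standard noisy study-like session: 100 saccades, 0.02 deg noise,
    blinks and pursuit, seed 1."""
    spec = sk.standard_session_spec(n_saccades=100, seed=1)
    trace, truth = sk.make_session(spec)
    return spec, trace, truth


@pytest.fixture(scope="session")
def reference_detection(reference_session):
    spec, trace, truth = reference_session
    speed = sk.preprocess_trace(trace)
    accepted, rejected = sk.detect_saccades(speed)
    return speed, accepted, rejected, truth


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free 50-saccade session without blinks or pursuit, seed 7."""
    spec = sk.standard_session_spec(
        n_saccades=50, seed=7, measurement_noise_sd=0.0, fixation_noise_sd=0.0,
        with_blinks=False, with_pursuit=False,
    )
    trace, truth = sk.make_session(spec)
    return spec, trace, truth
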