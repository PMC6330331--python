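"""Curvature and velocity-profile deviation: oracles, invariances, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saccadekit as sk
from saccadekit import model
from saccadekit.errors import DegeneratePathError, InsufficientDataError
from saccadekit.metrics import fit_displacement_series, pointwise_curvature
from saccadekit.synth import SaccadeSpec


def curvature_oracle(x, y):
    """Literal loop transcription of the pointwise-curvature definition:
    norm of the second difference over total path length, median over t."""
    T = len(x)
    denom = 0.0
    for t in range(1, T):
        denom += math.sqrt((x[t] - x[t - 1]) ** 2 + (y[t] - y[t - 1]) ** 2)
    kts = []
    for t in range(1, T - 1):
        num = math.sqrt(
            (x[t + 1] - 2 * x[t] + x[t - 1]) ** 2 + (y[t + 1] - 2 * y[t] + y[t - 1]) ** 2
        )
        kts.append(num / denom)
    kts = sorted(kts)
    m = len(kts)
    return kts[m // 2] if m % 2 else 0.5 * (kts[m // 2 - 1] + kts[m // 2])


class TestCurvature:
    @pytest.mark.parametrize("variant", ["as_written", "perpendicular"])
    def test_collinear_equally_spaced_points_have_zero_curvature(self, variant):
        x = np.arange(30.0)
        y = np.zeros(30)
        res = pointwise_curvature(x, y, variant=variant)
        assert res.k == 0.0
        assert (res.pointwise == 0.0).all()

    @pytest.mark.parametrize("scale", [0.1, 1.0, 7.3])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(size=40))
        y = np.cumsum(rng.normal(size=40))
        base = pointwise_curvature(x, y).k
        scaled = pointwise_curvature(scale * x, scale * y).k
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_quarter_circle_matches_brute_force_oracle(self):
        theta = np.linspace(0, np.pi / 2, 30)
        x = 2.0 * np.cos(theta)
        y = 2.0 * np.sin(theta)
        res = pointwise_curvature(x, y)
        assert res.k == pytest.approx(curvature_oracle(x, y), abs=1e-12)

    def test_median_is_used_not_mean(self):
        # a path with one sharp corner: mean k_t is inflated, median is not
        x = np.concatenate([np.arange(10.0), np.full(10, 9.0)])
        y = np.concatenate([np.zeros(10), np.arange(1.0, 11.0)])
        res = pointwise_curvature(x, y)
        assert res.k == pytest.approx(float(np.median(res.pointwise)), abs=0)
        assert res.k < float(np.mean(res.pointwise))

    @pytest.mark.parametrize("variant", ["as_written", "perpendicular"])
    def test_rigid_motion_and_scaling_invariance_on_random_paths(self, variant):
        rng = np.random.default_rng(12345)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            x = np.cumsum(rng.normal(size=n))
            y = np.cumsum(rng.normal(size=n))
            k0 = pointwise_curvature(x, y, variant=variant).k
            ang = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(ang), np.sin(ang)
            scale = rng.uniform(0.2, 5.0)
            dx, dy = rng.normal(size=2) * 10
            xr = scale * (c * x - s * y) + dx
            yr = scale * (s * x + c * y) + dy
            k1 = pointwise_curvature(xr, yr, variant=variant).k
            assert abs(k1 - k0) < 1e-10

    def test_bowed_saccades_have_increasing_perpendicular_curvature(self):
        ks = []
        for bow in np.arange(0.0, 1.0, 0.1):
            spec = SaccadeSpec(onset_ms=0, magnitude=5, direction=30, p2=11, p3=2,
                               bow_amplitude=bow)
            _, x, y = sk.make_saccade_trajectory(spec, 1000)
            ks.append(pointwise_curvature(x, y, variant="perpendicular").k)
        assert all(a < b for a, b in zip(ks, ks[1:]))

    def test_straight_path_nonuniform_speed_separates_the_variants(self):
        # varying traversal speed on a straight line: the as_written numerator
        # keeps the tangential acceleration, the perpendicular variant drops it
        t = np.linspace(0, 1, 25)
        x = t**2
        y = np.zeros_like(x)
        assert pointwise_curvature(x, y, variant="as_written").k > 0
        assert pointwise_curvature(x, y, variant="perpendicular").k == 0.0

    def test_degenerate_inputs_raise(self):
        with pytest.raises(InsufficientDataError):
            pointwise_curvature([0, 1, 2], [0, 0, 0])
        with pytest.raises(DegeneratePathError):
            pointwise_curvature(np.zeros(10), np.zeros(10))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_curvature_nonnegative_and_scale_free_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        x = np.cumsum(rng.normal(size=n))
        y = np.cumsum(rng.normal(size=n))
        res = pointwise_curvature(x, y)
        assert (res.pointwise >= 0).all()
        assert res.k == pytest.approx(pointwise_curvature(2.0 * x, 2.0 * y).k, rel=1e-9)


class TestProfileFit:
    def _event_from_trajectory(self, spec, noise_sd=0.0, seed=0):
        session = sk.SessionSpec(
            duration_ms=spec.onset_ms + spec.duration_ms + 300,
            saccades=[spec],
            measurement_noise_sd=noise_sd,
            seed=seed,
        )
        trace, _ = sk.make_session(session)
        speed = sk.preprocess_trace(trace)
        accepted, _ = sk.detect_saccades(speed)
        assert len(accepted) == 1
        return accepted[0], speed

    def test_self_consistency_on_noiseless_model_trajectory(self):
        spec = SaccadeSpec(onset_ms=0, magnitude=5, direction=0, p2=10, p3=2)
        t, x, y = sk.make_saccade_trajectory(spec, 1000)
        d = np.hypot(x - x[0], y - y[0])
        p1, p2, p3, conv = fit_displacement_series(d, t)
        assert conv
        assert p1 == pytest.approx(5.0, rel=1e-2)
        assert p2 == pytest.approx(10.0, rel=1e-2)
        assert p3 == pytest.approx(2.0, rel=1e-2)

    def test_standard_exponential_recovers_shape_one(self):
        t = np.arange(0.0, 61.0)
        d = 5.0 * (1.0 - np.exp(-t / 10.0))
        p1, p2, p3, conv = fit_displacement_series(d, t, init_duration=60.0)
        assert conv
        assert p3 == pytest.approx(1.0, abs=1e-6)
        assert p1 == pytest.approx(5.0, rel=1e-6)

    def test_deviation_zero_when_speed_matches_model(self):
        # raw (unsmoothed) model trajectory: measured and fitted velocity
        # series coincide, so the deviation collapses to numerical noise
        spec = SaccadeSpec(onset_ms=0, magnitude=6, direction=45, p2=11, p3=2)
        t, x, y = sk.make_saccade_trajectory(spec, 1000)
        pad = 60
        tt = np.arange(len(t) + 2 * pad, dtype=float)
        xx = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
        yy = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        speed = sk.compute_speed(sk.GazeTrace(tt, xx, yy, np.ones(len(tt), dtype=bool)))
        from saccadekit.detect import segment

        candidates = segment(speed)
        assert len(candidates) == 1
        ev = candidates[0]
        ev.onset_idx, ev.offset_idx = pad, pad + len(t) - 1  # full true support
        fit = sk.fit_profile(ev, speed)
        assert fit.deviation >= 0.0
        assert fit.deviation < 1e-3

    def test_deviation_floor_of_detected_events_is_small(self):
        # the detected event starts at the 30 deg/s crossing, not the true
        # onset, so even a noiseless model saccade keeps a small residual
        spec = SaccadeSpec(onset_ms=100, magnitude=6, direction=45, p2=11, p3=2)
        ev, speed = self._event_from_trajectory(spec)
        fit = sk.fit_profile(ev, speed)
        assert 0.0 <= fit.deviation < 2e-2

    def test_deviation_matches_grid_refined_oracle_on_noisy_saccade(self):
        spec = SaccadeSpec(onset_ms=100, magnitude=6, direction=20, p2=12, p3=2)
        ev, speed = self._event_from_trajectory(spec, noise_sd=0.02, seed=4)
        fit = sk.fit_profile(ev, speed)
        # independent oracle: coarse grid search + Nelder-Mead polish on the
        # same position-domain objective, then the same deviation definition
        sl = slice(ev.onset_idx, ev.offset_idx + 1)
        x = speed.smoothed_x[sl]
        y = speed.smoothed_y[sl]
        t = speed.sample_times[sl] - speed.sample_times[ev.onset_idx]
        d = np.hypot(x - x[0], y - y[0])

        def sse(p):
            return float(np.sum((model.displacement(t, *p) - d) ** 2))

        best = None
        for p1 in np.linspace(0.5 * ev.magnitude_deg, 2 * ev.magnitude_deg, 12):
            for p2 in np.linspace(2, 2 * ev.duration_ms, 15):
                for p3 in np.linspace(0.5, 4, 12):
                    v = sse((p1, p2, p3))
                    if best is None or v < best[0]:
                        best = (v, (p1, p2, p3))
        from scipy.optimize import minimize

        res = minimize(sse, best[1], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
        # same deviation definition (extended central differences), different
        # optimizer route
        t_ext = np.concatenate([[t[0] - 1.0], t, [t[-1] + 1.0]])
        f_ext = np.where(t_ext <= 0, 0.0,
                         model.displacement(np.maximum(t_ext, 0.0), *res.x))
        modeled = np.gradient(f_ext, t_ext)[1:-1]
        oracle_dev = float(np.sqrt(np.mean((speed.speed[sl] - modeled) ** 2)))
        assert fit.deviation == pytest.approx(oracle_dev, rel=0.02)

    def test_fit_independent_of_start_position_and_direction(self):
        fits = []
        for direction, x0, y0 in [(0, 0, 0), (120, 5, -3), (275, -8, 2)]:
            spec = SaccadeSpec(onset_ms=100, magnitude=6, direction=direction, p2=11,
                               p3=2, start_x=x0, start_y=y0)
            ev, speed = self._event_from_trajectory(spec)
            fits.append(sk.fit_profile(ev, speed))
        for f in fits[1:]:
            assert f.p1 == pytest.approx(fits[0].p1, rel=1e-6)
            assert f.p2 == pytest.approx(fits[0].p2, rel=1e-6)
            assert f.p3 == pytest.approx(fits[0].p3, rel=1e-6)
            assert f.deviation == pytest.approx(fits[0].deviation, rel=1e-6)

    def test_too_short_event_raises(self):
        t = np.arange(5.0)
        with pytest.raises(InsufficientDataError):
            fit_displacement_series(t * 0.1, t)

    def test_analytic_residual_variant_reports_discretization_floor(self):
        spec = SaccadeSpec(onset_ms=100, magnitude=6, direction=0, p2=11, p3=2)
        ev, speed = self._event_from_trajectory(spec)
        discrete = sk.fit_profile(ev, speed, velocity_residual="discrete")
        analytic = sk.fit_profile(ev, speed, velocity_residual="analytic")
        assert analytic.deviation >= discrete.deviation
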