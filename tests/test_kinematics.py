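"""Kinematic metric correctness: polar conversion, the four trial metrics,
their invariances, and agreement of generator and metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirsmoco.kinematics import (
    TrajectoryTrace,
    angvel_error,
    compute_metrics,
    fit_circle,
    metrics_table,
    radius_error,
    radius_sd,
    to_polar,
    trim_trace,
)
from nirsmoco.synthetic_data import TrajectoryGroundTruth, gen_trajectory

from conftest import random_trace


def _trace_from_xy(t, x, y, r_o=1.0, w_o=1.0, center=(0.0, 0.0)):
    return TrajectoryTrace(t=t, x=x, y=y, hand="right", condition="RHCC",
                           center=center, guide_radius=r_o, guide_angular_velocity=w_o)


class TestToPolar:
    def test_pythagorean_radius(self):
        t = np.array([0.0, 1.0])
        tr = _trace_from_xy(t, np.array([3.0, 3.0]), np.array([4.0, 4.0]))
        assert to_polar(tr).r == pytest.approx([5.0, 5.0], abs=1e-15)

    @pytest.mark.parametrize("direction,sign", [("ccw", 1.0), ("cw", -1.0)])
    def test_uniform_rotation_angular_velocity(self, direction, sign):
        T = 4.0
        t = np.arange(0, 2 * T, 1 / 200)  # 200 Hz
        ang = sign * 2 * np.pi * t / T
        tr = _trace_from_xy(t, np.cos(ang), np.sin(ang))
        w = to_polar(tr).w
        assert np.allclose(w[1:-1], sign * np.pi / 2, atol=1e-6)

    def test_angle_unwrapped_continuous(self):
        t = np.arange(0, 8, 1 / 28.5)
        tr = _trace_from_xy(t, np.cos(2 * t), np.sin(2 * t))
        theta = to_polar(tr).theta
        assert np.max(np.abs(np.diff(theta))) < np.pi  # no 2*pi jumps

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            to_polar(_trace_from_xy(np.array([0.0]), np.array([1.0]), np.array([0.0])))


class TestMetricFormulas:
    def test_constant_radius_gives_zero_sdr(self):
        t = np.arange(0, 4, 1 / 28.5)
        tr = _trace_from_xy(t, np.cos(t), np.sin(t))
        assert radius_sd(to_polar(tr)) == pytest.approx(0.0, abs=1e-12)

    def test_sdr_hand_computed_example(self):
        # radii {1,1,3,3}: mean 2, population SD exactly 1
        p = to_polar(_trace_from_xy(
            np.arange(4.0), np.array([1.0, 0.0, -3.0, 0.0]),
            np.array([0.0, 1.0, 0.0, -3.0])))
        assert radius_sd(p) == pytest.approx(1.0, abs=1e-12)

    def test_re_hand_computed_examples(self):
        p = to_polar(_trace_from_xy(np.arange(2.0), np.array([0.0, 2.0]),
                                    np.array([0.0, 0.0])))
        assert radius_error(p, 1.0) == pytest.approx(1.0, abs=1e-12)
        p2 = to_polar(_trace_from_xy(np.arange(2.0), np.array([2.0, 0.0]),
                                     np.array([0.0, 2.0])))
        assert radius_error(p2, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_population_divisor_oracle(self, rng):
        """All four metrics match an independent two-pass evaluation."""
        for _ in range(50):
            tr = random_trace(rng)
            p = to_polar(tr)
            n = p.n
            sdr = np.sqrt(np.sum((p.r - np.sum(p.r) / n) ** 2) / n)
            re = np.sqrt(np.sum((p.r - tr.guide_radius) ** 2) / n)
            sdav = np.sqrt(np.sum((p.w - np.sum(p.w) / n) ** 2) / n)
            ave = np.sqrt(np.sum((p.w - tr.guide_angular_velocity) ** 2) / n)
            m = compute_metrics(tr)
            assert m.sdr == pytest.approx(sdr, abs=1e-12)
            assert m.re == pytest.approx(re, abs=1e-12)
            assert m.sdav == pytest.approx(sdav, abs=1e-12)
            assert m.ave == pytest.approx(ave, abs=1e-12)

    def test_bias_variance_identity(self, rng):
        """RE^2 = SDR^2 + (rbar - r_o)^2 with divisor-n forms."""
        for _ in range(50):
            tr = random_trace(rng)
            p = to_polar(tr)
            re = radius_error(p, tr.guide_radius)
            sdr = radius_sd(p)
            assert re**2 == pytest.approx(sdr**2 + (p.mean_radius - tr.guide_radius) ** 2,
                                          abs=1e-12)

    def test_invalid_references_rejected(self, rng):
        p = to_polar(random_trace(rng))
        with pytest.raises(ValueError):
            radius_error(p, 0.0)
        with pytest.raises(ValueError):
            angvel_error(p, 0.0)


class TestInvariances:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(dx=st.floats(-10, 10), dy=st.floats(-10, 10), seed=st.integers(0, 2**16))
    def test_translation_invariance(self, dx, dy, seed):
        tr = random_trace(np.random.default_rng(seed))
        shifted = TrajectoryTrace(
            t=tr.t, x=tr.x + dx, y=tr.y + dy, hand=tr.hand, condition=tr.condition,
            center=(dx, dy), guide_radius=tr.guide_radius,
            guide_angular_velocity=tr.guide_angular_velocity)
        m0, m1 = compute_metrics(tr), compute_metrics(shifted)
        assert m1.sdr == pytest.approx(m0.sdr, rel=1e-9, abs=1e-12)
        assert m1.re == pytest.approx(m0.re, rel=1e-9, abs=1e-12)
        assert m1.ave == pytest.approx(m0.ave, rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi), seed=st.integers(0, 2**16))
    def test_rotation_invariance(self, angle, seed):
        tr = random_trace(np.random.default_rng(seed))
        c, s = np.cos(angle), np.sin(angle)
        rot = TrajectoryTrace(
            t=tr.t, x=c * tr.x - s * tr.y, y=s * tr.x + c * tr.y,
            hand=tr.hand, condition=tr.condition, guide_radius=tr.guide_radius,
            guide_angular_velocity=tr.guide_angular_velocity)
        m0, m1 = compute_metrics(tr), compute_metrics(rot)
        for f in ("sdr", "re", "sdav", "ave"):
            assert getattr(m1, f) == pytest.approx(getattr(m0, f), rel=1e-9, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 2**16))
    def test_scale_equivariance_of_length_metrics(self, scale, seed):
        tr = random_trace(np.random.default_rng(seed))
        scaled = TrajectoryTrace(
            t=tr.t, x=scale * tr.x, y=scale * tr.y, hand=tr.hand,
            condition=tr.condition, guide_radius=scale * tr.guide_radius,
            guide_angular_velocity=tr.guide_angular_velocity)
        m0, m1 = compute_metrics(tr), compute_metrics(scaled)
        assert m1.sdr == pytest.approx(scale * m0.sdr, rel=1e-9)
        assert m1.re == pytest.approx(scale * m0.re, rel=1e-9)


class TestGeneratorMetricRoundTrip:
    def test_noiseless_circle_scores_zero(self):
        gt = TrajectoryGroundTruth()
        m = compute_metrics(gen_trajectory(gt, 12.0, 100.0, seed=0))
        assert m.sdr == pytest.approx(0.0, abs=1e-9)
        assert m.re == pytest.approx(0.0, abs=1e-9)
        assert m.sdav == pytest.approx(0.0, abs=1e-9)
        assert m.ave == pytest.approx(0.0, abs=1e-9)

    def test_constant_radius_bias_appears_exactly_in_re(self):
        gt = TrajectoryGroundTruth(radius_bias=0.5)
        m = compute_metrics(gen_trajectory(gt, 12.0, 28.5, seed=0))
        assert m.re == pytest.approx(0.5, abs=1e-12)
        assert m.sdr == pytest.approx(0.0, abs=1e-12)

    def test_radius_noise_drives_mean_re_to_sigma(self):
        """With unbiased radial noise of SD sigma, RE estimates sigma."""
        sigma, n_trials = 0.1, 40
        gt = TrajectoryGroundTruth(radius_noise_sd=sigma)
        res = [compute_metrics(gen_trajectory(gt, 12.0, 28.5, seed=k)).re
               for k in range(n_trials)]
        n = int(12.0 * 28.5)
        tol = 3 * sigma / np.sqrt(2 * n * n_trials)
        assert np.mean(res) == pytest.approx(sigma, abs=3 * tol)

    def test_clockwise_direction_flips_angular_velocity_sign(self):
        gt = TrajectoryGroundTruth(direction="clockwise")
        tr = gen_trajectory(gt, 12.0, 100.0, seed=0)
        assert tr.guide_angular_velocity < 0
        assert np.all(to_polar(tr).w[1:-1] < 0)


class TestHelpers:
    def test_trim_removes_lead_and_trail(self):
        gt = TrajectoryGroundTruth()
        tr = gen_trajectory(gt, 12.0, 28.5, seed=0)
        trimmed = trim_trace(tr, 0.5, 0.5)
        assert trimmed.t[0] >= tr.t[0] + 0.5 - 1e-9
        assert trimmed.t[-1] <= tr.t[-1] - 0.5 + 1e-9

    def test_circle_fit_recovers_center_and_radius(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 100)
        cx, cy, r = 2.0, -1.0, 1.5
        x = cx + r * np.cos(theta)
        y = cy + r * np.sin(theta)
        fit = fit_circle(x, y)
        assert fit == pytest.approx((cx, cy, r), abs=1e-9)

    def test_metrics_table_schema(self, rng):
        traces = [random_trace(rng) for _ in range(3)]
        df = metrics_table(traces, trim_s=None)
        assert list(df.columns) == ["subject", "condition", "hand", "trial",
                                    "sdr", "re", "sdav", "ave", "n"]
        assert len(df) == 3
        assert (df[["sdr", "re", "sdav", "ave"]] >= 0).all().all()
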