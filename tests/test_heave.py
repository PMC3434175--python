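"""Heave dynamics, cue-channel calibrations, target paths, tracking runs."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cuefidelity import (
    ControllerSpec,
    CueChannelParams,
    DivergenceError,
    DomainError,
    HeaveParams,
    SeriesAlignmentError,
    TargetPathSpec,
    cue_channels,
    fly_tracking_run,
    simulate_heave,
    target_path,
)

FIVE_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5)


def step_input(level, n=600, onset=100):
    u = np.zeros(n)
    u[onset:] = level
    return u


class TestSimulateHeave:
    def test_equilibrium(self):
        tr = simulate_heave(HeaveParams(), np.zeros(100))
        assert np.all(tr.w == 0) and np.all(tr.height == 0) and np.all(tr.accel == 0)

    def test_constant_input_closed_form(self):
        p = HeaveParams(zw=-0.5, z0=4.8, dt=0.01)
        tr = simulate_heave(p, np.full(3001, 0.5))
        w_exact = (-p.z0 / p.zw) * 0.5 * (1 - np.exp(p.zw * tr.t))
        rel = np.abs(tr.w[1:] - w_exact[1:]) / np.abs(w_exact[1:])
        assert rel.max() < 1e-6
        # steady state -Z0/Zw * Xc = 9.6 * 0.5
        assert tr.w[-1] == pytest.approx(4.8, rel=1e-6)

    @pytest.mark.parametrize("zw,t63", [(-0.1, 10.0), (-0.5, 2.0)])
    def test_time_constant(self, zw, t63):
        p = HeaveParams(zw=zw, dt=0.01)
        n = int(t63 / p.dt) + 1
        tr = simulate_heave(p, np.full(n, 0.3))
        w_ss = (-p.z0 / p.zw) * 0.3
        assert tr.w[-1] / w_ss == pytest.approx(1 - np.exp(-1), rel=1e-6)

    @given(scale=st.floats(0.1, 5), seed=st.integers(0, 100))
    def test_linearity(self, scale, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, 0.5, 200)
        p = HeaveParams()
        a = simulate_heave(p, u)
        b = simulate_heave(p, scale * u)
        assert np.allclose(b.w, scale * a.w, rtol=1e-9, atol=1e-12)
        assert np.allclose(b.height, scale * a.height, rtol=1e-9, atol=1e-12)

    def test_velocity_bounded_by_steady_state(self, rng):
        p = HeaveParams(zw=-0.1)
        u = rng.uniform(-1.5, 1.5, 5000)
        tr = simulate_heave(p, u)
        assert np.max(np.abs(tr.w)) <= (-p.z0 / p.zw) * 1.5 + 1e-9

    def test_unstable_damping_rejected(self):
        with pytest.raises(DomainError):
            HeaveParams(zw=0.1)

    def test_non_uniform_grid_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        with pytest.raises(SeriesAlignmentError):
            simulate_heave(HeaveParams(), np.zeros(4), t=t)


class TestCueChannels:
    def test_audio_excursion_over_full_travel(self):
        cues = CueChannelParams()
        xc = np.linspace(-cues.collective_range / 2, cues.collective_range / 2, 301)
        tr = cue_channels(simulate_heave(HeaveParams(), xc), cues)
        assert tr.audio_db.max() - tr.audio_db.min() == pytest.approx(3.0)
        assert tr.audio_db.min() == pytest.approx(86.0)
        assert tr.audio_db.max() == pytest.approx(89.0)

    def test_static_mode_constant(self):
        cues = CueChannelParams()
        tr = cue_channels(
            simulate_heave(HeaveParams(), step_input(0.4)), cues, audio_mode="static"
        )
        assert np.all(tr.audio_db == 87.5)

    def test_substitute_mode_same_mapping(self):
        cues = CueChannelParams()
        u = step_input(0.4)
        a = cue_channels(simulate_heave(HeaveParams(), u), cues, audio_mode="variable")
        b = cue_channels(simulate_heave(HeaveParams(), u), cues, audio_mode="substitute")
        assert np.array_equal(a.audio_db, b.audio_db)

    def test_peak_acceleration_slope(self):
        cues = CueChannelParams()
        peaks = []
        for level in FIVE_LEVELS:
            tr = cue_channels(simulate_heave(HeaveParams(), step_input(level)), cues)
            peaks.append(np.max(np.abs(tr.platform_accel_g)))
        slope = np.polyfit(FIVE_LEVELS, peaks, 1)[0]
        assert slope == pytest.approx(0.04, rel=0.01)

    def test_motion_channel_latency(self):
        cues = CueChannelParams()
        p = HeaveParams()
        tr = cue_channels(simulate_heave(p, step_input(0.3, onset=100)), cues)
        onset = int(np.argmax(np.abs(tr.platform_accel_g) > 1e-12))
        assert (onset - 100) * p.dt == pytest.approx(cues.motion_delay, abs=p.dt)

    def test_offgrid_delay_warns_and_rounds(self, caplog):
        cues = CueChannelParams(motion_delay=0.083)
        with caplog.at_level(logging.WARNING, logger="cuefidelity.heave"):
            tr = cue_channels(simulate_heave(HeaveParams(), step_input(0.3)), cues)
        assert "not a multiple" in caplog.text
        onset = int(np.argmax(np.abs(tr.platform_accel_g) > 1e-12))
        assert onset - 100 == 8  # nearest sample

    def test_washout_removes_sustained_component(self):
        cues = CueChannelParams(washout_tc=1.0)
        tr = cue_channels(simulate_heave(HeaveParams(), step_input(0.3, n=5000)), cues)
        assert abs(tr.platform_accel_g[-1]) < 1e-3


class TestTargetPath:
    def test_flat_when_amplitudes_zero(self):
        spec = TargetPathSpec(amplitudes=(0,) * 6, duration=10)
        assert np.all(target_path(spec).height == 0)

    def test_single_sinusoid_identity(self):
        spec = TargetPathSpec(
            n_components=1, amplitudes=(1.0,), phases=(0.0,),
            frequencies=(0.2,), duration=20.0,
        )
        path = target_path(spec)
        # quarter period of omega = 0.2 rad/s at t = pi / 0.4
        assert path.height_at(np.pi / 0.4) == pytest.approx(1.0)

    def test_amplitude_triangle_inequality_and_determinism(self):
        a = target_path(TargetPathSpec(seed=5, duration=30))
        b = target_path(TargetPathSpec(seed=5, duration=30))
        assert np.max(np.abs(a.height)) <= a.amplitudes.sum() + 1e-12
        assert np.array_equal(a.height, b.height)

    def test_frequencies_outside_range_rejected(self):
        with pytest.raises(DomainError):
            target_path(TargetPathSpec(frequencies=(0.1,) * 6))

    def test_analytic_velocity_matches_numeric(self):
        path = target_path(TargetPathSpec(seed=2, duration=30))
        num = np.gradient(path.height, path.t)
        ana = path.velocity_at(path.t)
        assert np.allclose(num[5:-5], ana[5:-5], atol=1e-3)


@pytest.fixture(scope="module")
def short_path():
    return target_path(TargetPathSpec(duration=60.0, dt=0.01, seed=3))


class TestFlyTrackingRun:
    def test_ideal_inverse_tracks_perfectly(self, short_path):
        run = fly_tracking_run(
            HeaveParams(zw=-0.5), CueChannelParams(), short_path,
            ControllerSpec(kind="ideal_inverse"),
        )
        assert run.median_abs_error < 1e-8

    def test_easy_dynamics_beat_hard(self, short_path):
        cues = CueChannelParams()
        ctrl = ControllerSpec(seed=11)
        errs = {}
        for zw in (-0.1, -0.5):
            errs[zw] = fly_tracking_run(
                HeaveParams(zw=zw), cues, short_path, ctrl, motion_on=False,
                turbine_on=False,
            ).median_abs_error
        assert errs[-0.5] < errs[-0.1]

    def test_motion_platform_reduces_error(self, short_path):
        cues = CueChannelParams()
        for seed in range(3):
            ctrl = ControllerSpec(seed=seed)
            on = fly_tracking_run(
                HeaveParams(), cues, short_path, ctrl, motion_on=True
            ).median_abs_error
            off = fly_tracking_run(
                HeaveParams(), cues, short_path, ctrl, motion_on=False
            ).median_abs_error
            assert on <= off

    def test_trained_audio_substitutes_for_motion(self, short_path):
        cues = CueChannelParams()
        ctrl = ControllerSpec(seed=4, audio_skill=0.85)
        with_turbine = fly_tracking_run(
            HeaveParams(), cues, short_path, ctrl, motion_on=False, turbine_on=True
        ).median_abs_error
        without = fly_tracking_run(
            HeaveParams(), cues, short_path, ctrl, motion_on=False, turbine_on=False
        ).median_abs_error
        assert with_turbine < without

    def test_unstable_gains_diverge(self, short_path):
        # sign-flipped proportional gain is positive feedback: the collective
        # saturates and the aircraft runs away from the target
        ctrl = ControllerSpec(kind="proportional_delay", kp=-5.0, seed=0)
        with pytest.raises(DivergenceError):
            fly_tracking_run(HeaveParams(), CueChannelParams(), short_path, ctrl)

    def test_determinism(self, short_path):
        ctrl = ControllerSpec(seed=9)
        a = fly_tracking_run(HeaveParams(), CueChannelParams(), short_path, ctrl)
        b = fly_tracking_run(HeaveParams(), CueChannelParams(), short_path, ctrl)
        assert a.median_abs_error == b.median_abs_error
        assert np.array_equal(a.flown, b.flown)
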