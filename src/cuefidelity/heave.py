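"""Single-axis heave (vertical) flight dynamics with auditory and kinematic cue channels.

The simulated aircraft is a first-order velocity lag driven by the collective
control input Xc (inches):

    dw/dt = Zw * w + Z0 * Xc        (vertical velocity w)
    dh/dt = w                       (altitude h, ft)

with input gain ``Z0 = 4.8`` and damping ``Zw = -0.1`` ("hard" dynamics) or
``Zw = -0.5`` ("easy").  For a constant input from rest the closed-form
response is w(t) = (-Z0/Zw) * Xc * (1 - exp(Zw t)) with time constant 1/|Zw|.

Three cue channels are derived from the state:

* audio — turbine level in dB, proportional to Xc (3 dB excursion over the
  full collective travel, centred on 87.5 dB(A)); a ``static`` mode holds the
  level constant and a ``substitute`` mode applies the same mapping to a
  different carrier (a label only — no audio is rendered);
* motion — platform acceleration in g, calibrated to a peak-acceleration
  slope of 0.04 g per unit Xc and delayed by 80 ms, with an optional
  first-order washout high-pass;
* visual — the altitude itself (consumed by the tracking controllers).

Closed-loop tracking runs fly a sum-of-sinusoids target path with a simple
proportional(-derivative) pilot whose state-estimate noise depends on which
cues are available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError, DomainError, SeriesAlignmentError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeaveParams:
    """Flight-dynamics parameters: dw/dt = zw*w + z0*Xc."""

    z0: float = 4.8
    zw: float = -0.1
    dt: float = 0.01

    def __post_init__(self):
        if not self.zw < 0:
            raise DomainError(f"zw must be < 0 (stable damping), got {self.zw}")
        if not self.dt > 0:
            raise DomainError(f"dt must be > 0, got {self.dt}")


@dataclass(frozen=True)
class CueChannelParams:
    """Calibration of the audio and motion cue channels.

    ``collective_range`` is the full Xc travel (inches); the default 3.0
    corresponds to +-1.5 in about centre, over which the turbine level sweeps
    ``audio_range_db`` (3 dB: 86-89 dB(A)).
    """

    audio_range_db: float = 3.0
    audio_base_db: float = 87.5
    collective_range: float = 3.0
    motion_gain: float = 0.04     # g per unit Xc, peak-acceleration slope
    motion_delay: float = 0.080   # s
    washout_tc: float = 0.0       # s; 0 disables the high-pass stub

    def __post_init__(self):
        if self.collective_range <= 0:
            raise DomainError("collective_range must be > 0")
        if self.motion_delay < 0 or self.washout_tc < 0:
            raise DomainError("motion_delay and washout_tc must be >= 0")


@dataclass
class HeaveTrace:
    """Simulated state and cue-channel time series on a uniform grid."""

    t: np.ndarray
    Xc: np.ndarray
    accel: np.ndarray
    w: np.ndarray
    height: np.ndarray
    params: HeaveParams
    audio_db: np.ndarray | None = None
    platform_accel_g: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "Xc": self.Xc, "accel": self.accel,
                "w": self.w, "height": self.height}
        if self.audio_db is not None:
            data["audio_db"] = self.audio_db
        if self.platform_accel_g is not None:
            data["platform_accel_g"] = self.platform_accel_g
        return pd.DataFrame(data)


def _rk4_step(z0, zw, w, h, u0, u_half, u1, dt):
    """One RK4 step of (w, h) with linearly interpolated control."""
    def f(wv, u):
        return zw * wv + z0 * u

    k1w = f(w, u0)
    k1h = w
    k2w = f(w + 0.5 * dt * k1w, u_half)
    k2h = w + 0.5 * dt * k1w
    k3w = f(w + 0.5 * dt * k2w, u_half)
    k3h = w + 0.5 * dt * k2w
    k4w = f(w + dt * k3w, u1)
    k4h = w + dt * k3w
    w_next = w + dt / 6.0 * (k1w + 2 * k2w + 2 * k3w + k4w)
    h_next = h + dt / 6.0 * (k1h + 2 * k2h + 2 * k3h + k4h)
    return w_next, h_next


def simulate_heave(
    params: HeaveParams,
    control: Sequence[float],
    t: Sequence[float] | None = None,
    w0: float = 0.0,
    h0: float = 0.0,
) -> HeaveTrace:
    """Integrate the heave model under a sampled control input.

    ``control`` must be sampled on a uniform grid with step ``params.dt``
    (pass ``t`` to have the grid verified).  Fixed-step RK4; against the
    constant-input closed form the relative velocity error is far below 1e-6
    at dt = 0.01 s.
    """
    u = np.asarray(control, dtype=float)
    if u.ndim != 1 or u.size < 2:
        raise DomainError("control must be a 1-D signal with >= 2 samples")
    if t is not None:
        t = np.asarray(t, dtype=float)
        if t.shape != u.shape:
            raise SeriesAlignmentError("t and control lengths differ")
        steps = np.diff(t)
        if not np.allclose(steps, params.dt, rtol=1e-9, atol=1e-12):
            raise SeriesAlignmentError(
                "control must be sampled uniformly at params.dt; resample first"
            )
    n = u.size
    tgrid = np.arange(n) * params.dt if t is None else t
    w = np.empty(n)
    h = np.empty(n)
    w[0], h[0] = w0, h0
    dt = params.dt
    for i in range(n - 1):
        u_half = 0.5 * (u[i] + u[i + 1])
        w[i + 1], h[i + 1] = _rk4_step(
            params.z0, params.zw, w[i], h[i], u[i], u_half, u[i + 1], dt
        )
    accel = params.zw * w + params.z0 * u
    return HeaveTrace(t=tgrid, Xc=u, accel=accel, w=w, height=h, params=params)


AUDIO_MODES = ("variable", "static", "substitute")


def cue_channels(trace: HeaveTrace, cues: CueChannelParams,
                 audio_mode: str = "variable") -> HeaveTrace:
    """Fill the audio and motion cue channels of a simulated trace.

    audio_db is linear in Xc with slope ``audio_range_db / collective_range``
    (``substitute`` uses the same mapping on a different carrier; ``static``
    holds the base level).  platform_accel_g is the model acceleration
    normalised by Z0 and scaled by ``motion_gain`` — so a ramp to |Xc| peaks
    at exactly ``motion_gain * |Xc|`` g — delayed by ``motion_delay``.
    """
    if audio_mode not in AUDIO_MODES:
        raise DomainError(f"audio_mode must be one of {AUDIO_MODES}")
    if audio_mode == "static":
        audio = np.full_like(trace.Xc, cues.audio_base_db)
    else:
        slope = cues.audio_range_db / cues.collective_range
        audio = cues.audio_base_db + slope * trace.Xc

    dt = trace.params.dt
    shift_exact = cues.motion_delay / dt
    shift = int(round(shift_exact))
    if abs(shift_exact - shift) > 1e-9:
        logger.warning(
            "motion_delay %.4f s is not a multiple of dt %.4f s; "
            "shifting by the nearest %d samples", cues.motion_delay, dt, shift
        )
    platform = cues.motion_gain * trace.accel / trace.params.z0
    if shift > 0:
        platform = np.concatenate([np.zeros(shift), platform[:-shift]])
    if cues.washout_tc > 0:
        from scipy.signal import lfilter
        alpha = cues.washout_tc / (cues.washout_tc + dt)
        platform = lfilter([alpha, -alpha], [1.0, -alpha], platform)

    trace.audio_db = audio
    trace.platform_accel_g = platform
    return trace


@dataclass(frozen=True)
class TargetPathSpec:
    """Sum-of-sinusoids target height profile.

    Six components with frequencies spanning 0.2-0.5 rad/s, each with its own
    amplitude and phase; amplitudes/phases not given explicitly are drawn once
    from the seed (amplitudes uniform on [0.5, 1.5] ft, phases on [0, 2pi)),
    making the path reproducible yet too complex to memorise.
    """

    n_components: int = 6
    freq_range: tuple[float, float] = (0.2, 0.5)
    amplitudes: tuple[float, ...] | None = None
    phases: tuple[float, ...] | None = None
    frequencies: tuple[float, ...] | None = None
    duration: float = 120.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0:
            raise DomainError("duration and dt must be > 0")
        if self.n_components < 1:
            raise DomainError("n_components must be >= 1")


@dataclass
class TargetPath:
    """Realised target path with analytic derivatives."""

    amplitudes: np.ndarray
    omegas: np.ndarray
    phases: np.ndarray
    t: np.ndarray
    height: np.ndarray

    def height_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        h = (self.amplitudes * np.sin(np.multiply.outer(t, self.omegas) + self.phases)).sum(-1)
        return h if h.ndim else float(h)

    def velocity_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        v = (self.amplitudes * self.omegas
             * np.cos(np.multiply.outer(t, self.omegas) + self.phases)).sum(-1)
        return v if v.ndim else float(v)

    def accel_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        a = -(self.amplitudes * self.omegas ** 2
              * np.sin(np.multiply.outer(t, self.omegas) + self.phases)).sum(-1)
        return a if a.ndim else float(a)


def target_path(spec: TargetPathSpec) -> TargetPath:
    """Build the seeded sum-of-sinusoids target path."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.freq_range
    if spec.frequencies is not None:
        omegas = np.asarray(spec.frequencies, dtype=float)
    elif spec.n_components == 1:
        omegas = np.array([lo])
    else:
        omegas = np.linspace(lo, hi, spec.n_components)
    if np.any(omegas < lo - 1e-12) or np.any(omegas > hi + 1e-12):
        raise DomainError("frequencies must lie within freq_range")
    amps = (np.asarray(spec.amplitudes, float) if spec.amplitudes is not None
            else rng.uniform(0.5, 1.5, spec.n_components))
    phases = (np.asarray(spec.phases, float) if spec.phases is not None
              else rng.uniform(0.0, 2 * np.pi, spec.n_components))
    if not (len(amps) == len(phases) == len(omegas)):
        raise DomainError("amplitudes, phases and frequencies must have equal length")
    t = np.arange(int(round(spec.duration / spec.dt)) + 1) * spec.dt
    path = TargetPath(amplitudes=amps, omegas=omegas, phases=phases, t=t,
                      height=np.empty(0))
    path.height = path.height_at(t)
    return path


CONTROLLER_KINDS = ("proportional_delay", "proportional_derivative_delay", "ideal_inverse")


@dataclass(frozen=True)
class ControllerSpec:
    """Synthetic pilot flying the heave model against a target path.

    Both closed-loop kinds command a trim feedforward ``-zw * target_vel / z0``
    (pilots rapidly feel the steady collective the damping demands) plus a
    proportional correction on the perceived height error; with a 0.2 s visual
    delay that loop is oscillation-limited, most severely in the
    lightly-damped "hard" dynamics.  ``proportional_derivative_delay``
    additionally damps the perceived error rate — but only to the extent a
    velocity cue is available:

    * motion platform on — velocity is sensed directly (noise ``sigma_w``)
      and the full derivative gain ``kd`` applies;
    * platform off, turbine informative and ``audio_skill`` > 0 — a trained
      pilot propagates a forward-model velocity from their own control inputs
      via the turbine cue, recovering ``audio_skill``-scaled damping;
    * neither — no usable velocity estimate; the loop degrades to the
      proportional law.

    ``ideal_inverse`` applies the exact model-inverting feedforward with no
    delay or noise (a perfect-tracking reference).  The visual height carries
    noise ``sigma_h`` (reduced 30% when the auditory error beep localises the
    target).  ``audio_skill`` in [0, 1]; untrained pilots ignore the turbine.
    """

    kind: str = "proportional_derivative_delay"
    kp: float = 0.08
    kd: float = 0.25
    visual_delay: float = 0.2     # s
    sigma_h: float = 0.3          # ft, visual height noise
    sigma_w: float = 0.05         # ft/s, platform velocity-sense noise
    audio_skill: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CONTROLLER_KINDS:
            raise DomainError(f"controller kind must be one of {CONTROLLER_KINDS}")
        if not 0.0 <= self.audio_skill <= 1.0:
            raise DomainError("audio_skill must be in [0, 1]")


@dataclass
class TrackingRun:
    """One closed-loop tracking run and its performance score."""

    t: np.ndarray
    target: np.ndarray
    flown: np.ndarray
    Xc: np.ndarray
    median_abs_error: float
    condition: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "target": self.target, "flown": self.flown})


_DIVERGENCE_BOUND = 200.0  # ft


def fly_tracking_run(
    params: HeaveParams,
    cues: CueChannelParams,
    path: TargetPath,
    controller: ControllerSpec,
    motion_on: bool = True,
    turbine_on: bool = True,
    error_beep_on: bool = False,
) -> TrackingRun:
    """Fly the target path closed loop and score the run.

    The score is the median absolute height error in ft.  Deterministic given
    ``controller.seed``.  Raises :class:`DivergenceError` if the tracking
    error leaves a +-200 ft envelope (unstable gains).
    """
    dt = params.dt
    t = path.t
    n = t.size
    rng = np.random.default_rng(controller.seed)

    delay_steps = max(int(round(controller.visual_delay / dt)), 0)
    noise_h = rng.normal(0.0, controller.sigma_h, n)
    noise_w = rng.normal(0.0, controller.sigma_w, n)
    # auditory error beep sharpens the perceived height error slightly
    h_noise_scale = 0.7 if error_beep_on else 1.0

    target = path.height
    target_vel = path.velocity_at(t)
    half_travel = cues.collective_range / 2.0

    # velocity-cue gating of the derivative term
    if motion_on:
        kd_eff = controller.kd
    elif turbine_on and controller.audio_skill > 0:
        kd_eff = controller.kd * controller.audio_skill
    else:
        kd_eff = 0.0

    w = float(path.velocity_at(0.0))
    h = float(target[0])
    flown = np.empty(n)
    xc_log = np.empty(n)
    w_model = w  # pilot's forward-model velocity, propagated from own commands
    for i in range(n):
        flown[i] = h
        if abs(h - target[i]) > _DIVERGENCE_BOUND:
            raise DivergenceError(
                f"tracking error exceeded {_DIVERGENCE_BOUND} ft at t={t[i]:.2f} s "
                f"(kp={controller.kp}, kd={controller.kd})"
            )
        if controller.kind == "ideal_inverse":
            u = (path.accel_at(t[i]) - params.zw * path.velocity_at(t[i])) / params.z0
        else:
            j = max(i - delay_steps, 0)
            h_obs = flown[j] + h_noise_scale * noise_h[i]
            # trim feedforward: steady collective the damping demands
            u = -params.zw * target_vel[i] / params.z0
            u += controller.kp * (target[i] - h_obs)
            if controller.kind == "proportional_derivative_delay" and kd_eff > 0:
                if motion_on:
                    w_hat = w + noise_w[i]  # platform-sensed velocity
                else:
                    w_hat = w_model         # turbine-driven forward model
                u += kd_eff * (target_vel[i] - w_hat)
            u = float(np.clip(u, -half_travel, half_travel))
        xc_log[i] = u
        if i < n - 1:
            if controller.kind == "ideal_inverse":
                th = t[i] + 0.5 * dt
                u_half = (path.accel_at(th) - params.zw * path.velocity_at(th)) / params.z0
                t1 = t[i + 1]
                u1 = (path.accel_at(t1) - params.zw * path.velocity_at(t1)) / params.z0
            else:
                u_half = u1 = u  # zero-order hold within the step
            w, h = _rk4_step(params.z0, params.zw, w, h, u, u_half, u1, dt)
            w_model = w_model + dt * (params.zw * w_model + params.z0 * u)

    err = float(np.median(np.abs(target - flown)))
    return TrackingRun(
        t=t, target=target, flown=flown, Xc=xc_log, median_abs_error=err,
        condition={"motion_on": motion_on, "turbine_on": turbine_on,
                   "error_beep_on": error_beep_on, "zw": params.zw},
    )
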