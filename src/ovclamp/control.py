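"""Feedback laws of the optical clamp.

Two controllers act on the monochromator wavelength to hold the
bleach-corrected dF/F0 at a setpoint:

* a decision-tree I-controller: inside the tolerance band the wavelength is
  held; outside it moves by K_I * |error| in the direction given by the sign
  of the error times a user-selected increment polarity, clipped to the
  monochromator limits;
* a discrete PID controller around a fixed calibration wavelength, with
  optional scalar Kalman smoothing of the measured dF/F0 and
  Ziegler-Nichols tuning from the critical gain and oscillation period.

Status semantics: ``holding`` while inside the band, ``adapting`` while
moving, ``limit_reached`` when the command was clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "IControllerConfig",
    "PIDConfig",
    "ControllerState",
    "ZNTuning",
    "KalmanState",
    "i_step",
    "pid_step",
    "zn_tune",
    "kalman_step",
    "kalman_steady_state",
    "controller_preset",
    "HOLDING",
    "ADAPTING",
    "LIMIT_REACHED",
]

HOLDING = "holding"
ADAPTING = "adapting"
LIMIT_REACHED = "limit_reached"


@dataclass
class IControllerConfig:
    ki: float  # nm per % dF/F0, per frame
    tolerance: float  # % dF/F0
    lambda_min: float = 400.0  # nm
    lambda_max: float = 600.0  # nm
    increment_sign: int = 1  # user-selected polarity of i[k]
    start_wavelength: float = 520.0  # nm

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not self.lambda_min < self.lambda_max:
            raise ValueError("lambda_min must be < lambda_max")
        if not self.lambda_min <= self.start_wavelength <= self.lambda_max:
            raise ValueError("start_wavelength outside wavelength limits")
        if self.increment_sign not in (1, -1):
            raise ValueError("increment_sign must be +1 or -1")


@dataclass
class PIDConfig:
    kp: float  # nm per %
    ki: float  # nm per (% * s)
    kd: float  # nm * s per %
    ta: float  # s, sampling period
    lambda0: float  # nm, calibration wavelength
    tolerance: float = 0.0  # % (band inside which status is 'holding')
    lambda_min: float = 400.0
    lambda_max: float = 600.0

    def __post_init__(self) -> None:
        if self.ta <= 0:
            raise ValueError("ta must be > 0")


@dataclass
class ControllerState:
    wavelength: float  # nm
    error: float = 0.0  # % (e)
    error_sum: float = 0.0  # % (e_sum, PID integral memory)
    error_prev: float = 0.0  # % (e_{t-1})
    status: str = HOLDING


@dataclass
class ZNTuning:
    """Ziegler-Nichols closed-loop tuning from the critical gain and period.

    kp = 0.6*kp_crit, Tn = 0.5*t_crit, Tv = 0.12*t_crit, with
    ki = kp/Tn and kd = kp*Tv.
    """

    kp_crit: float
    t_crit: float  # s

    def __post_init__(self) -> None:
        if self.kp_crit <= 0 or self.t_crit <= 0:
            raise ValueError("kp_crit and t_crit must be > 0")

    @property
    def kp(self) -> float:
        return 0.6 * self.kp_crit

    @property
    def tn(self) -> float:
        return 0.5 * self.t_crit

    @property
    def tv(self) -> float:
        return 0.12 * self.t_crit

    @property
    def ki(self) -> float:
        return self.kp / self.tn

    @property
    def kd(self) -> float:
        return self.kp * self.tv


@dataclass
class KalmanState:
    """Scalar Kalman filter with constant system dynamics (A = H = 1)."""

    x_hat: float  # % estimate
    p: float  # estimate variance
    q: float  # system-noise covariance Q
    r: float  # measurement-noise covariance R
    a: float = 1.0
    h: float = 1.0
    k_gain: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 0:
            raise ValueError("p must be >= 0")


def i_step(
    state: ControllerState, dff: float, target: float, config: IControllerConfig
) -> ControllerState:
    """One decision-tree I-controller update.

    Inside the (inclusive) tolerance band the wavelength is unchanged and the
    status is ``holding``; otherwise the wavelength moves by ki*|e| in the
    direction increment_sign*sign(target - dff), clipped to the limits.
    A non-finite measurement holds the previous wavelength.
    """
    if not math.isfinite(dff):
        return replace(state, status=HOLDING)
    diff = target - dff
    e = abs(diff)
    if e <= config.tolerance:
        return replace(state, error=e, status=HOLDING)
    direction = config.increment_sign * (1 if diff > 0 else -1)
    lam = state.wavelength + config.ki * e * direction
    clipped = lam < config.lambda_min or lam > config.lambda_max
    lam = min(max(lam, config.lambda_min), config.lambda_max)
    return replace(
        state,
        wavelength=lam,
        error=e,
        status=LIMIT_REACHED if clipped else ADAPTING,
    )


def pid_step(
    state: ControllerState,
    dff: float,
    target: float,
    config: PIDConfig,
    kalman: KalmanState | None = None,
) -> tuple[ControllerState, KalmanState | None]:
    """One discrete PID update around the calibration wavelength.

    u = kp*e + ki*Ta*e_sum + kd*(e - e_prev)/Ta, with signed error
    e = target - dff, and wavelength = lambda0 + u clipped to the limits.
    If a Kalman state is given, the measurement is smoothed first and the
    updated filter state returned alongside.  The integral memory is frozen
    while the command is clipped (anti-windup).
    """
    if not math.isfinite(dff):
        return replace(state, status=HOLDING), kalman
    if kalman is not None:
        kalman = kalman_step(kalman, dff)
        dff = kalman.x_hat
    e = target - dff
    e_sum = state.error_sum + e
    u = config.kp * e + config.ki * config.ta * e_sum + config.kd * (e - state.error_prev) / config.ta
    lam = config.lambda0 + u
    clipped = lam < config.lambda_min or lam > config.lambda_max
    if clipped:
        e_sum = state.error_sum  # anti-windup: do not accumulate while saturated
        lam = min(max(lam, config.lambda_min), config.lambda_max)
    if abs(e) <= config.tolerance:
        status = HOLDING
    else:
        status = LIMIT_REACHED if clipped else ADAPTING
    return (
        ControllerState(
            wavelength=lam, error=e, error_sum=e_sum, error_prev=e, status=status
        ),
        kalman,
    )


def zn_tune(kp_crit: float, t_crit: float) -> ZNTuning:
    """Ziegler-Nichols gains from the measured critical gain and period (s)."""
    return ZNTuning(kp_crit=kp_crit, t_crit=t_crit)


def kalman_step(state: KalmanState, z: float) -> KalmanState:
    """Scalar predict/correct cycle.

    x* = A x_hat, P* = A P A + Q; S = H P* H + R, K = P* H / S;
    x_hat <- x* + K (z - H x*), P <- (1 - K H) P*.
    """
    if state.r <= 0:
        raise ValueError("measurement-noise covariance r must be > 0")
    a, h = state.a, state.h
    x_star = a * state.x_hat
    p_star = a * state.p * a + state.q
    s = h * p_star * h + state.r
    if s <= 0:
        raise ValueError("non-positive innovation covariance")
    k = p_star * h / s
    x_hat = x_star + k * (z - h * x_star)
    p = (1.0 - k * h) * p_star
    return replace(state, x_hat=x_hat, p=p, k_gain=k, s=s)


def kalman_steady_state(q: float, r: float) -> tuple[float, float, float]:
    """Stationary solution of the scalar filter with A = H = 1.

    Returns (prior variance p*, posterior variance p, gain k):
    the algebraic Riccati fixed point gives the prior
    p* = (q + sqrt(q^2 + 4 q r)) / 2, with k = p*/(p* + r) and posterior
    p = (1 - k) p*.
    """
    p_prior = (q + math.sqrt(q * q + 4.0 * q * r)) / 2.0
    k_inf = p_prior / (p_prior + r)
    p_post = (1.0 - k_inf) * p_prior
    return p_prior, p_post, k_inf


def find_critical_gain(
    plant,
    sensor,
    target: float = 3.0,
    kp_values=tuple(round(1.0 * 1.3**k, 2) for k in range(16)),
    n_frames: int = 300,
    calibration_frames: int = 400,
    start_wavelength: float = 520.0,
) -> tuple[float, float]:
    """Ziegler-Nichols experiment: ramp the proportional gain on the given
    plant until the closed loop sustains oscillation, and measure its period.

    Runs a P-only controller (ki = kd = 0, zero tolerance) at each candidate
    gain, noise-free; oscillation is declared sustained when the error peaks
    in the last third of the run do not decay.  Returns (kp_crit, t_crit_s).
    """
    from dataclasses import replace as _replace

    import numpy as np

    from .session import ProtocolSpec, run_session

    plant = _replace(plant, noise_sd=0.0)
    for kp in kp_values:
        cfg = PIDConfig(
            kp=kp,
            ki=0.0,
            kd=0.0,
            ta=sensor.frame_period / 1000.0,
            lambda0=start_wavelength,
        )
        proto = ProtocolSpec(
            targets=[target],
            frames_per_step=n_frames,
            calibration_frames=calibration_frames,
            seed=0,
        )
        res = run_session(proto, plant, sensor, cfg)
        err = res.dff_pct[res.clamp_slice()] - target
        tail = err[n_frames // 3 :]
        # sustained oscillation: sign alternation with non-decaying envelope
        crossings = np.flatnonzero(np.diff(np.sign(tail)) != 0)
        if crossings.size < 6:
            continue
        half = tail.size // 2
        a1 = float(np.abs(tail[:half]).max())
        a2 = float(np.abs(tail[half:]).max())
        if a2 < 0.5 * a1 or a2 < 0.05:
            continue
        # oscillation period from mean spacing of same-direction crossings
        period_frames = 2.0 * float(np.mean(np.diff(crossings)))
        return float(kp), period_frames * sensor.frame_period / 1000.0
    raise RuntimeError("no sustained oscillation within the gain grid")


def controller_preset(name: str) -> IControllerConfig:
    """Tissue defaults for the I-controller.

    The integral gain is an empirical per-tissue constant; the dynamic-clamp
    presets (pharynx, dvb) use a larger gain with a very tight tolerance
    (+-0.005%) so intrinsic spikes are counteracted within a frame or two.
    The start wavelength is the preset's compensation wavelength (net
    photocurrent zero at rest with the imaging laser on).
    """
    lam0 = compensation_wavelength(name)
    if name in ("pharynx", "dvb"):
        return IControllerConfig(ki=10.0, tolerance=0.005, start_wavelength=lam0)
    return IControllerConfig(ki=7.0, tolerance=1.0, start_wavelength=lam0)


def compensation_wavelength(preset_name: str) -> float:
    """Monochromator wavelength that re-zeros the net photocurrent at rest
    with the imaging laser on (counteracting its crosstalk onto the
    depolarizer), for the named plant preset."""
    from scipy.optimize import brentq

    from .plant import LightInput, make_preset, photocurrent, steady_state

    plant = make_preset(preset_name)

    def net(lam: float) -> float:
        light = LightInput(lam, 1.0, laser_on=True)
        return photocurrent(steady_state(light, plant), light, plant)

    return round(brentq(net, 400.0, 600.0, xtol=1e-3), 1)
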