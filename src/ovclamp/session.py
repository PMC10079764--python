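"""Closed-loop run orchestration and the results-file format.

A run has two phases.  During *calibration* the cell is illuminated with the
imaging laser plus the compensation (start) wavelength; the raw gray values
are collected, the bleaching exponential is fitted, and F0 is taken from the
first 50 corrected frames.  During the *clamp* phase the controller updates
the monochromator wavelength once per camera frame from the bleach-corrected
dF/F0.  The plant is integrated with fixed inner substeps between frames, so
a run is fully reproducible for a given seed.

Results are written as a UTF-8 text file: ``# key: value`` header lines
(protocol parameters, bleach fit a/b/c/R^2, frame rate) followed by a
tab-separated table ``frame time_ms gray_raw gray_corr dff_pct
wavelength_nm status`` with status codes C (calibration), H (holding),
A (adapting), L (limit reached).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bleach import (
    BaselineState,
    BleachFit,
    compute_dff,
    correct_frame,
    fit_bleach,
    make_baseline,
)
from .control import (
    ADAPTING,
    HOLDING,
    LIMIT_REACHED,
    ControllerState,
    IControllerConfig,
    KalmanState,
    PIDConfig,
    i_step,
    pid_step,
)
from .plant import LightInput, PlantConfig, initial_state, step_plant
from .sensor import SensorConfig, sample_frame

__all__ = [
    "ProtocolSpec",
    "Waveform",
    "SessionResult",
    "PseudoIVResult",
    "run_session",
    "run_pseudo_iv",
    "run_current_clamp",
    "run_on_the_run",
    "write_results",
    "read_results",
]

_STATUS_CODE = {
    "calibration": "C",
    HOLDING: "H",
    ADAPTING: "A",
    LIMIT_REACHED: "L",
}
_CODE_STATUS = {v: k for k, v in _STATUS_CODE.items()}

#: plant settling time before frame 0, ms (device warm-up at the start light)
_WARMUP_MS = 500.0


@dataclass
class ProtocolSpec:
    targets: list[float] = field(default_factory=lambda: [0.0, -5.0, 5.0, 0.0])
    frames_per_step: list[int] | int = 200
    calibration_frames: int = 2000
    kind: str = "steps"
    intensity: float = 1.0
    seed: int | None = None

    def step_frames(self) -> list[int]:
        if isinstance(self.frames_per_step, int):
            return [self.frames_per_step] * len(self.targets)
        if len(self.frames_per_step) != len(self.targets):
            raise ValueError("frames_per_step must match targets")
        return list(self.frames_per_step)


@dataclass
class Waveform:
    """Open-loop wavelength playback for the optical current-clamp mode.

    ``pulse``: monochromator off except one pulse of given wavelength and
    duration; ``steps``: a list of (wavelength, frames); ``ramp``: linear
    wavelength sweep over the clamp phase.
    """

    kind: str
    wavelength: float = 0.0  # pulse
    duration_ms: float = 0.0  # pulse
    pre_ms: float = 0.0  # pulse: dark time before the pulse
    total_frames: int = 0  # pulse/ramp
    steps: list[tuple[float, int]] | None = None
    lambda_start: float = 400.0  # ramp
    lambda_end: float = 600.0  # ramp
    intensity: float = 1.0

    def sequence(self, frame_period: float) -> tuple[np.ndarray, np.ndarray]:
        """(wavelength, intensity) per clamp frame."""
        if self.kind == "pulse":
            n = self.total_frames
            lam = np.full(n, self.wavelength)
            inten = np.zeros(n)
            i0 = int(round(self.pre_ms / frame_period))
            i1 = i0 + max(1, int(round(self.duration_ms / frame_period)))
            inten[i0:i1] = self.intensity
            return lam, inten
        if self.kind == "steps":
            lam = np.concatenate([np.full(n, w) for w, n in self.steps])
            return lam, np.full(lam.size, self.intensity)
        if self.kind == "ramp":
            lam = np.linspace(self.lambda_start, self.lambda_end, self.total_frames)
            return lam, np.full(lam.size, self.intensity)
        raise ValueError(f"unknown waveform kind {self.kind!r}")


@dataclass
class SessionResult:
    header: dict
    frame: np.ndarray
    time_ms: np.ndarray
    gray_raw: np.ndarray
    gray_corr: np.ndarray
    dff_pct: np.ndarray
    wavelength_nm: np.ndarray
    status: np.ndarray  # single-character codes
    voltage_mv: np.ndarray | None = None  # ground truth, simulation only
    bleach_fit: BleachFit | None = None
    baseline: BaselineState | None = None

    @property
    def calibration_frames(self) -> int:
        return int(self.header["calibration_frames"])

    def clamp_slice(self) -> slice:
        return slice(self.calibration_frames, len(self.frame))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "time_ms": self.time_ms,
                "gray_raw": self.gray_raw,
                "gray_corr": self.gray_corr,
                "dff_pct": self.dff_pct,
                "wavelength_nm": self.wavelength_nm,
                "status": self.status,
            }
        )

    def step_bounds(self) -> list[tuple[int, int]]:
        """Clamp-phase [start, stop) frame indices of each protocol step."""
        frames = [int(x) for x in str(self.header["frames_per_step"]).split(",")]
        start = self.calibration_frames
        out = []
        for n in frames:
            out.append((start, start + n))
            start += n
        return out

    def step_targets(self) -> list[float]:
        return [float(x) for x in str(self.header["targets"]).split(",")]


@dataclass
class PseudoIVResult:
    target_dff: np.ndarray  # %
    achieved_dff: np.ndarray  # %, mean of the last 25% of each step
    wavelength: np.ndarray  # nm, same window
    session: SessionResult | None = None


def _target_schedule(protocol: ProtocolSpec) -> np.ndarray:
    return np.repeat(
        np.asarray(protocol.targets, float), protocol.step_frames()
    )


def _simulate(
    plant: PlantConfig,
    sensor: SensorConfig,
    calibration_frames: int,
    n_clamp: int,
    start_wavelength: float,
    intensity: float,
    controller_step,
    open_loop: tuple[np.ndarray, np.ndarray] | None,
    seed: int | None,
    header_extra: dict,
) -> SessionResult:
    """Shared core loop for closed-loop and open-loop runs.

    ``controller_step(frame_idx, dff, state) -> state`` decides the next
    wavelength for closed-loop runs; ``open_loop`` provides per-frame
    (wavelength, intensity) for playback runs.
    """
    rng = np.random.default_rng(seed)
    n_total = calibration_frames + n_clamp
    fp = sensor.frame_period

    onsets = np.empty(0)
    ev = plant.event_generator
    cutoff = 0.0
    if ev is not None and ev.kind != "none":
        onsets = ev.onset_times(_WARMUP_MS + n_total * fp)
        cutoff = 8.0 * ev.tau_decay

    gray_raw = np.empty(n_total)
    wavelengths = np.empty(n_total)
    status = np.empty(n_total, dtype="U1")
    voltage = np.empty(n_total)

    state = initial_state(plant)
    light = LightInput(start_wavelength, intensity, laser_on=True)
    state = step_plant(state, light, 0.0, _WARMUP_MS, plant, rng, _window(onsets, state.time, _WARMUP_MS, cutoff))
    # re-anchor time so frame k is sampled at t = k * frame_period
    state = replace(state, time=0.0)

    for k in range(calibration_frames):
        state = step_plant(
            state, light, 0.0, fp, plant, rng, _window(onsets, state.time, fp, cutoff)
        )
        gray_raw[k] = sample_frame(state.voltage, k, sensor, rng).gray
        wavelengths[k] = start_wavelength
        status[k] = "C"
        voltage[k] = state.voltage

    fit = fit_bleach(gray_raw[:calibration_frames])
    if not np.all(np.isfinite([fit.a, fit.b, fit.c])) or fit.offset(n_total - 1) <= 0:
        raise RuntimeError(
            "degenerate bleach fit: cannot correct the clamp phase "
            f"(a={fit.a:.3g}, b={fit.b:.3g}, c={fit.c:.3g})"
        )
    if not fit.converged or fit.r_squared < 0.8:
        warnings.warn(
            f"bleach fit quality is low (R^2 = {fit.r_squared:.3f}); "
            "events during the calibration phase can cause this",
            stacklevel=2,
        )
    gray_corr = np.array(
        [correct_frame(g, k, fit) for k, g in enumerate(gray_raw[:calibration_frames])]
    )
    baseline = make_baseline(gray_corr, calibration_frames)
    dff = np.empty(n_total)
    dff[:calibration_frames] = (gray_corr - baseline.f0) / baseline.f0 * 100.0

    gray_corr = np.concatenate([gray_corr, np.empty(n_clamp)])

    ctrl = ControllerState(wavelength=start_wavelength)
    for j in range(n_clamp):
        k = calibration_frames + j
        if open_loop is not None:
            lam, inten = float(open_loop[0][j]), float(open_loop[1][j])
            st = "H"
        else:
            lam, inten = ctrl.wavelength, intensity
            st = None
        light = LightInput(lam, inten, laser_on=True)
        state = step_plant(
            state, light, 0.0, fp, plant, rng, _window(onsets, state.time, fp, cutoff)
        )
        g = sample_frame(state.voltage, k, sensor, rng).gray
        gc = correct_frame(g, k, fit)
        d = compute_dff(gc, baseline)
        if open_loop is None:
            ctrl = controller_step(j, d, ctrl)
            st = _STATUS_CODE[ctrl.status]
        gray_raw[k] = g
        gray_corr[k] = gc
        dff[k] = d
        wavelengths[k] = lam
        status[k] = st
        voltage[k] = state.voltage

    header = dict(header_extra)
    header.update({
        "calibration_frames": calibration_frames,
        "framerate_hz": round(sensor.fps, 6),
        "start_wavelength_nm": start_wavelength,
        "intensity": intensity,
        "seed": seed if seed is not None else "",
        "bleach_a": f"{fit.a:.6f}",
        "bleach_b": f"{fit.b:.8f}",
        "bleach_c": f"{fit.c:.6f}",
        "bleach_r2": f"{fit.r_squared:.6f}",
        "f0": f"{baseline.f0:.6f}",
    })
    frames = np.arange(n_total)
    return SessionResult(
        header=header,
        frame=frames,
        time_ms=frames * fp,
        gray_raw=gray_raw,
        gray_corr=gray_corr,
        dff_pct=dff,
        wavelength_nm=wavelengths,
        status=status,
        voltage_mv=voltage,
        bleach_fit=fit,
        baseline=baseline,
    )


def _window(onsets: np.ndarray, t0: float, dt: float, cutoff: float) -> np.ndarray:
    if onsets.size == 0:
        return onsets
    lo = np.searchsorted(onsets, t0 - cutoff)
    hi = np.searchsorted(onsets, t0 + dt)
    return onsets[lo:hi]


def run_session(
    protocol: ProtocolSpec,
    plant: PlantConfig,
    sensor: SensorConfig,
    controller: IControllerConfig | PIDConfig,
    kalman: KalmanState | None = None,
) -> SessionResult:
    """Run a step protocol in closed loop (tolerance-band I-controller by
    default, PID with optional Kalman smoothing if a PIDConfig is given)."""
    targets = _target_schedule(protocol)
    header = {
        "protocol": protocol.kind,
        "targets": ",".join(f"{t:g}" for t in protocol.targets),
        "frames_per_step": ",".join(str(n) for n in protocol.step_frames()),
        "tolerance_pct": getattr(controller, "tolerance", 0.0),
        "ki": controller.ki,
        "lambda_min_nm": controller.lambda_min,
        "lambda_max_nm": controller.lambda_max,
    }
    if isinstance(controller, PIDConfig):
        header["kp"] = controller.kp
        header["kd"] = controller.kd
        kalman_box = [kalman]

        def step(j, dff, ctrl):
            st, kalman_box[0] = pid_step(
                ctrl, dff, float(targets[j]), controller, kalman_box[0]
            )
            return st

        start = controller.lambda0
    else:

        def step(j, dff, ctrl):
            return i_step(ctrl, dff, float(targets[j]), controller)

        start = controller.start_wavelength
    return _simulate(
        plant,
        sensor,
        protocol.calibration_frames,
        int(targets.size),
        start,
        protocol.intensity,
        step,
        None,
        protocol.seed,
        header,
    )


def run_pseudo_iv(
    limits: tuple[float, float],
    plant: PlantConfig,
    sensor: SensorConfig,
    controller: IControllerConfig,
    frames_per_step: int = 200,
    calibration_frames: int = 2000,
    seed: int | None = None,
) -> PseudoIVResult:
    """Clamp dF/F0 in 11 consecutive equally spaced steps from the lower to
    the upper limit; report the mean achieved dF/F0 and wavelength over the
    last 25% of each step."""
    lower, upper = limits
    if not lower < upper:
        raise ValueError("lower limit must be < upper limit")
    targets = np.linspace(lower, upper, 11)
    protocol = ProtocolSpec(
        targets=list(targets),
        frames_per_step=frames_per_step,
        calibration_frames=calibration_frames,
        kind="pseudo_iv",
        seed=seed,
    )
    session = run_session(protocol, plant, sensor, controller)
    ach, lam = [], []
    for (i0, i1) in session.step_bounds():
        w = max(1, (i1 - i0) // 4)  # final 25%, rounded down, >= 1 frame
        ach.append(float(session.dff_pct[i1 - w : i1].mean()))
        lam.append(float(session.wavelength_nm[i1 - w : i1].mean()))
    return PseudoIVResult(
        target_dff=targets,
        achieved_dff=np.array(ach),
        wavelength=np.array(lam),
        session=session,
    )


def run_current_clamp(
    waveform: Waveform,
    plant: PlantConfig,
    sensor: SensorConfig,
    start_wavelength: float = 520.0,
    calibration_frames: int = 2000,
    lambda_min: float = 400.0,
    lambda_max: float = 600.0,
    intensity: float = 1.0,
    seed: int | None = None,
) -> SessionResult:
    """Open-loop wavelength playback with full bleach-corrected dF/F0
    recording (the purely optical analogue of a current clamp)."""
    lam, inten = waveform.sequence(sensor.frame_period)
    active = lam[inten > 0]
    if active.size and (active.min() < lambda_min or active.max() > lambda_max):
        raise ValueError("waveform outside the wavelength limits")
    header = {
        "protocol": "current_clamp",
        "targets": "",
        "frames_per_step": str(lam.size),
        "waveform": waveform.kind,
    }
    return _simulate(
        plant,
        sensor,
        calibration_frames,
        int(lam.size),
        start_wavelength,
        intensity,
        None,
        (lam, inten),
        seed,
        header,
    )


def run_on_the_run(
    target_schedule: list[tuple[float, float]],
    n_frames: int,
    plant: PlantConfig,
    sensor: SensorConfig,
    controller: IControllerConfig,
    calibration_frames: int = 2000,
    seed: int | None = None,
) -> SessionResult:
    """Closed-loop run whose holding value changes live at scheduled times.

    ``target_schedule`` is a list of (time_ms, target_pct) with increasing
    times, time 0 = start of the clamp phase; each change takes effect at
    the frame boundary at or after its scheduled time.
    """
    times = [t for t, _ in target_schedule]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("schedule times must be increasing")
    fp = sensor.frame_period
    targets = np.empty(n_frames)
    targets[:] = target_schedule[0][1]
    for t_ms, tgt in target_schedule:
        i0 = int(np.ceil(t_ms / fp))
        targets[min(i0, n_frames) :] = tgt

    header = {
        "protocol": "on_the_run",
        "targets": ",".join(f"{t:g}" for _, t in target_schedule),
        "frames_per_step": str(n_frames),
        "tolerance_pct": controller.tolerance,
        "ki": controller.ki,
        "lambda_min_nm": controller.lambda_min,
        "lambda_max_nm": controller.lambda_max,
        "schedule_ms": ",".join(f"{t:g}" for t, _ in target_schedule),
    }

    def step(j, dff, ctrl):
        return i_step(ctrl, dff, float(targets[j]), controller)

    return _simulate(
        plant,
        sensor,
        calibration_frames,
        n_frames,
        controller.start_wavelength,
        1.0,
        step,
        None,
        seed,
        header,
    )


# ---------------------------------------------------------------------------
# results-file I/O


def write_results(result: SessionResult, path_or_buf) -> None:
    """Write the results text file (header + TSV table)."""
    buf = io.StringIO()
    for key, value in result.header.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("frame\ttime_ms\tgray_raw\tgray_corr\tdff_pct\twavelength_nm\tstatus\n")
    for i in range(len(result.frame)):
        buf.write(
            f"{result.frame[i]}\t{result.time_ms[i]:.3f}\t{result.gray_raw[i]:.1f}\t"
            f"{result.gray_corr[i]:.3f}\t{result.dff_pct[i]:.6f}\t"
            f"{result.wavelength_nm[i]:.4f}\t{result.status[i]}\n"
        )
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_results(path_or_buf) -> SessionResult:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines(keepends=True)
    else:
        with open(path_or_buf, encoding="utf-8") as fh:
            lines = fh.readlines()
    header: dict = {}
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        key, _, value = lines[i][1:].partition(":")
        header[key.strip()] = value.strip()
        i += 1
    df = pd.read_csv(io.StringIO("".join(lines[i:])), sep="\t", dtype={"status": str})
    return SessionResult(
        header=header,
        frame=df["frame"].to_numpy(),
        time_ms=df["time_ms"].to_numpy(),
        gray_raw=df["gray_raw"].to_numpy(),
        gray_corr=df["gray_corr"].to_numpy(),
        dff_pct=df["dff_pct"].to_numpy(),
        wavelength_nm=df["wavelength_nm"].to_numpy(),
        status=df["status"].to_numpy(dtype="U1"),
    )
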