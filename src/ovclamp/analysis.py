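"""Offline statistics for optical-clamp traces.

Covers the calibration regressions that translate optical readings into
electrophysiological units (dF/F0 -> mV, wavelength -> pA, fitted by OLS
with heteroscedasticity-consistent standard errors and a White test),
control-quality metrics (transition times, tolerance-band fractions,
binned r.m.s. deviation, saturation fraction), action-potential detection
(amplitude, FWHM, rise time constant) and optical I/V difference curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_white

from .session import PseudoIVResult, SessionResult

__all__ = [
    "RegressionFit",
    "APStats",
    "ControlQuality",
    "DEFAULT_VOLTAGE_CALIBRATION",
    "DEFAULT_CURRENT_CALIBRATION",
    "fit_calibration",
    "dff_to_mv",
    "wavelength_to_pa",
    "transition_time",
    "control_quality",
    "detect_aps",
    "aligned_event_amplitudes",
    "difference_iv",
    "simulate_voltage_calibration",
    "simulate_current_calibration",
]


@dataclass
class RegressionFit:
    intercept: float
    slope: float
    robust_se_intercept: float = float("nan")
    robust_se_slope: float = float("nan")
    r_squared: float = float("nan")
    white_test_p: float = float("nan")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


#: reference membrane-potential-vs-dF/F0 calibration (mV = a + b * %dF/F0)
DEFAULT_VOLTAGE_CALIBRATION = RegressionFit(intercept=-30.27, slope=2.25, r_squared=0.8)
#: reference current-vs-wavelength calibration (pA = a + b * nm, patch-clamp
#: sign convention: inward currents negative)
DEFAULT_CURRENT_CALIBRATION = RegressionFit(intercept=607.06, slope=-1.21, r_squared=0.8)


def fit_calibration(x, y) -> RegressionFit:
    """OLS line with White/HC0 robust standard errors and White test p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    exog = sm.add_constant(x)
    res = sm.OLS(y, exog).fit(cov_type="HC0")
    try:
        _, white_p, _, _ = het_white(res.resid, exog)
    except Exception:
        white_p = float("nan")
    return RegressionFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        robust_se_intercept=float(res.bse[0]),
        robust_se_slope=float(res.bse[1]),
        r_squared=float(res.rsquared),
        white_test_p=float(white_p),
    )


def dff_to_mv(dff, fit: RegressionFit = DEFAULT_VOLTAGE_CALIBRATION):
    """Convert %dF/F0 to membrane potential (mV) via the calibration line."""
    return fit.predict(dff)


def wavelength_to_pa(wavelength, fit: RegressionFit = DEFAULT_CURRENT_CALIBRATION):
    """Convert wavelength (nm) to photocurrent (pA, patch convention)."""
    return fit.predict(wavelength)


# ---------------------------------------------------------------------------
# control quality


@dataclass
class ControlQuality:
    transition_times: list[float]  # ms per step; nan where never entered
    within_tol_fraction: float
    within_half_tol_fraction: float
    rmsd_timecourse: np.ndarray  # % per time bin (transitions excluded)
    saturation_fraction: float


def transition_time(
    trace: SessionResult, step_index: int, tolerance: float | None = None
) -> float:
    """Time (ms) from the step's first frame to the first frame inside the
    tolerance band; 0 if already inside, NaN if the band is never entered."""
    bounds = trace.step_bounds()
    if not 0 <= step_index < len(bounds):
        raise IndexError("no such step")
    i0, i1 = bounds[step_index]
    target = trace.step_targets()[step_index]
    if tolerance is None:
        tolerance = float(trace.header["tolerance_pct"])
    dev = np.abs(trace.dff_pct[i0:i1] - target)
    inside = np.flatnonzero(dev <= tolerance)
    if inside.size == 0:
        return float("nan")
    return float(inside[0] * (trace.time_ms[1] - trace.time_ms[0]))


def control_quality(
    trace: SessionResult, tolerance: float | None = None, bin_ms: float = 100.0
) -> ControlQuality:
    """Tolerance-band statistics over the clamp phase.

    Fractions are computed over all clamp-phase frames; the binned r.m.s.
    deviation excludes each step's transition period (frames before the
    band is first entered).  Saturation is the fraction of frames whose
    status is L (wavelength clipped at the monochromator limits).
    """
    if tolerance is None:
        tolerance = float(trace.header["tolerance_pct"])
    bounds = trace.step_bounds()
    targets = trace.step_targets()
    fp = trace.time_ms[1] - trace.time_ms[0]

    dev_all = []
    dev_settled = []
    t_settled = []
    transitions = []
    for (i0, i1), tgt in zip(bounds, targets):
        dev = np.abs(trace.dff_pct[i0:i1] - tgt)
        dev_all.append(dev)
        inside = np.flatnonzero(dev <= tolerance)
        if inside.size == 0:
            transitions.append(float("nan"))
            continue
        transitions.append(float(inside[0] * fp))
        dev_settled.append(dev[inside[0] :])
        t_settled.append(trace.time_ms[i0 + inside[0] : i1])

    dev_all = np.concatenate(dev_all)
    n = dev_all.size
    within = float(np.mean(dev_all <= tolerance)) if n else 0.0
    within_half = float(np.mean(dev_all <= tolerance / 2.0)) if n else 0.0

    sl = trace.clamp_slice()
    saturation = float(np.mean(trace.status[sl] == "L")) if n else 0.0

    if dev_settled:
        devs = np.concatenate(dev_settled)
        ts = np.concatenate(t_settled)
        t0 = trace.time_ms[trace.calibration_frames]
        bins = ((ts - t0) // bin_ms).astype(int)
        rmsd = np.array(
            [math.sqrt(np.mean(devs[bins == b] ** 2)) for b in np.unique(bins)]
        )
    else:
        rmsd = np.empty(0)

    return ControlQuality(
        transition_times=transitions,
        within_tol_fraction=within,
        within_half_tol_fraction=within_half,
        rmsd_timecourse=rmsd,
        saturation_fraction=saturation,
    )


# ---------------------------------------------------------------------------
# action potentials


@dataclass
class APStats:
    amplitude: float  # trace units (% dF/F0 or mV)
    fwhm: float  # ms
    rise_tau: float  # ms
    peak_time: float  # ms


def detect_aps(time, value, min_prominence: float) -> list[APStats]:
    """Detect action-potential-like events in a uniformly sampled trace.

    Peaks are found by prominence; the amplitude is the prominence above the
    local baseline (peak minus prominence); FWHM comes from linearly
    interpolated half-maximum crossings; the rise time constant from an
    exponential fit to the 10-90% rising flank.  Detection is invariant to
    time translation and baseline shifts.
    """
    from scipy.signal import find_peaks

    t = np.asarray(time, float)
    v = np.asarray(value, float)
    if t.size != v.size:
        raise ValueError("time and value must have equal length")
    if t.size < 3:
        return []
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trace must be uniformly sampled")

    peaks, props = find_peaks(v, prominence=min_prominence)
    out: list[APStats] = []
    for idx, peak in enumerate(peaks):
        amp = float(props["prominences"][idx])
        base = v[peak] - amp
        half = base + amp / 2.0

        # half-maximum crossings with linear interpolation
        i = peak
        while i > 0 and v[i - 1] > half:
            i -= 1
        if i == 0:
            t_lo = t[0]
        else:
            t_lo = t[i - 1] + (half - v[i - 1]) / (v[i] - v[i - 1]) * (t[i] - t[i - 1])
        j = peak
        while j < v.size - 1 and v[j + 1] > half:
            j += 1
        if j == v.size - 1:
            t_hi = t[-1]
        else:
            t_hi = t[j] + (v[j] - half) / (v[j] - v[j + 1]) * (t[j + 1] - t[j])
        fwhm = float(t_hi - t_lo)

        out.append(
            APStats(
                amplitude=amp,
                fwhm=fwhm,
                rise_tau=_rise_tau(t, v, peak, base, amp),
                peak_time=float(t[peak]),
            )
        )
    return out


def aligned_event_amplitudes(
    time,
    value,
    onsets,
    baseline_window_ms: tuple[float, float] = (100.0, 10.0),
    peak_window_ms: float = 250.0,
) -> np.ndarray:
    """Event amplitudes from traces aligned at known onset times.

    For each onset, the amplitude is the maximum within ``peak_window_ms``
    after it minus the median over the pre-onset baseline window.  Robust to
    slow baseline drift (unlike prominence-based detection), which is how
    aligned spontaneous-vs-clamped comparisons are done.
    """
    t = np.asarray(time, float)
    v = np.asarray(value, float)
    lo_ms, hi_ms = baseline_window_ms
    out = []
    for t0 in onsets:
        base = v[(t >= t0 - lo_ms) & (t <= t0 - hi_ms)]
        peak = v[(t >= t0) & (t <= t0 + peak_window_ms)]
        if base.size == 0 or peak.size == 0:
            continue
        out.append(float(peak.max() - np.median(base)))
    return np.asarray(out)


def _rise_tau(t, v, peak, base, amp) -> float:
    # exponential fit of the 10-90% rising flank: ln(amp - (v-base)) linear in t
    lo_level = base + 0.1 * amp
    hi_level = base + 0.9 * amp
    i = peak
    while i > 0 and v[i - 1] > lo_level:
        i -= 1
    seg = slice(i, peak + 1)
    vv = v[seg]
    tt = t[seg]
    mask = (vv >= lo_level) & (vv <= hi_level)
    if mask.sum() < 2:
        return float("nan")
    resid = amp - (vv[mask] - base)
    resid = np.clip(resid, 1e-12 * amp, None)
    slope = np.polyfit(tt[mask], np.log(resid), 1)[0]
    if slope >= 0:
        return float("nan")
    return float(-1.0 / slope)


# ---------------------------------------------------------------------------
# optical I/V


def difference_iv(
    iv_a: PseudoIVResult,
    iv_b: PseudoIVResult,
    capacitance: float,
    voltage_fit: RegressionFit = DEFAULT_VOLTAGE_CALIBRATION,
    current_fit: RegressionFit = DEFAULT_CURRENT_CALIBRATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Capacitance-normalized extra intrinsic current of curve a relative to b.

    At each clamp step the steady-state photocurrent (deduced from the
    wavelength through the current calibration) balances the intrinsic
    currents; the additional intrinsic current of a relative to b is
    therefore minus the photocurrent difference.  Returns the voltage axis
    (mV, mean of both converted dF/F0 curves) and the difference current in
    pA/pF.
    """
    if iv_a.target_dff.shape != iv_b.target_dff.shape or not np.allclose(
        iv_a.target_dff, iv_b.target_dff
    ):
        raise ValueError("mismatched step-target grids")
    if capacitance <= 0:
        raise ValueError("capacitance must be > 0")
    mv = 0.5 * (
        dff_to_mv(iv_a.achieved_dff, voltage_fit)
        + dff_to_mv(iv_b.achieved_dff, voltage_fit)
    )
    i_a = wavelength_to_pa(iv_a.wavelength, current_fit)
    i_b = wavelength_to_pa(iv_b.wavelength, current_fit)
    return mv, (i_b - i_a) / capacitance


# ---------------------------------------------------------------------------
# synthetic calibration experiments (paired optical/electrical observations)


def _noise_scale_for_r2(signal: np.ndarray, weights: np.ndarray, r2: float) -> float:
    signal_var = float(np.var(signal))
    noise_var = signal_var * (1.0 / r2 - 1.0)
    return math.sqrt(noise_var / float(np.mean(weights**2)))


def simulate_voltage_calibration(
    n: int = 80, seed: int | None = None, target_r2: float = 0.8
):
    """Paired (dF/F0 target, measured membrane voltage) observations.

    Clamp targets cycle through the 11 steps spanning -5..+5 %; the true
    voltage at each step is the closed-loop fixed point of the reference
    body-wall-muscle plant (found by inverting its static light-to-voltage
    map), and the electrode reading adds heteroscedastic cell-to-cell noise
    sized to give the requested R^2.  Returns (x_dff, y_mv, generating_slope).
    """
    from scipy.optimize import brentq

    from .plant import LightInput, make_preset, static_voltage
    from .sensor import sensor_preset

    rng = np.random.default_rng(seed)
    plant = make_preset("bwm")
    sensor = sensor_preset("bwm")
    steps = np.linspace(-5.0, 5.0, 11)

    def static_dff(lam: float) -> float:
        v = static_voltage(LightInput(lam, 1.0, laser_on=True), plant)
        return sensor.dff_per_mv * (v - sensor.reference_voltage)

    lam_steps = np.array(
        [brentq(lambda l: static_dff(l) - s, 400.0, 600.0, xtol=1e-6) for s in steps]
    )
    v_steps = np.array(
        [static_voltage(LightInput(l, 1.0, laser_on=True), plant) for l in lam_steps]
    )
    idx = np.arange(n) % steps.size
    x = steps[idx]
    v_true = v_steps[idx]
    slope = float(np.polyfit(x, v_true, 1)[0])
    weights = 1.0 + 0.3 * np.abs(x)
    s0 = _noise_scale_for_r2(v_true, weights, target_r2)
    y = v_true + rng.normal(0.0, s0 * weights)
    return x, y, slope


def simulate_current_calibration(
    n: int = 72, seed: int | None = None, target_r2: float = 0.8
):
    """Paired (wavelength, voltage-clamp photocurrent) observations.

    Wavelength steps cycle over a 420-580 nm grid with the reference
    body-wall-muscle plant held at its resting potential; the measured
    current is reported in the patch-clamp convention (inward negative)
    with heteroscedastic noise sized to the requested R^2.
    Returns (x_nm, y_pa, generating_slope).
    """
    from .plant import LightInput, make_preset, photocurrent, steady_state

    rng = np.random.default_rng(seed)
    plant = make_preset("bwm")
    grid = np.linspace(420.0, 580.0, 9)
    idx = np.arange(n) % grid.size
    x = grid[idx]
    i_true = np.array(
        [
            -photocurrent(
                steady_state(LightInput(l, 1.0, laser_on=False), plant),
                LightInput(l, 1.0, laser_on=False),
                plant,
            )
            for l in x
        ]
    )
    slope = float(np.polyfit(x, i_true, 1)[0])
    weights = 1.0 + 0.3 * np.abs(x - x.mean()) / np.ptp(x)
    s0 = _noise_scale_for_r2(i_true, weights, target_r2)
    y = i_true + rng.normal(0.0, s0 * weights)
    return x, y, slope
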