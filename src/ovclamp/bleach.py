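"""Photobleaching correction and relative-fluorescence computation.

During the calibration phase the raw gray values are fitted with a single
exponential plus offset, a*exp(-b*frame) + c; every subsequent frame is
multiplied by the ratio of the fitted offset at frame 0 to the fitted offset
at that frame, which removes a multiplicative exponential decay exactly.
The resting fluorescence F0 is the mean of the first 50 corrected frames,
computed at the end of the calibration phase, and dF/F0 is reported in
percent relative to it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BleachFit",
    "BaselineState",
    "fit_bleach",
    "correct_frame",
    "compute_dff",
    "make_baseline",
]


@dataclass
class BleachFit:
    a: float  # ADU
    b: float  # per-frame decay rate
    c: float  # ADU
    r_squared: float
    converged: bool = True

    def offset(self, frame: int | np.ndarray):
        return self.a * np.exp(-self.b * np.asarray(frame, float)) + self.c


@dataclass
class BaselineState:
    f0: float  # ADU, resting fluorescence
    calibration_frames: int
    f0_window: int = 50

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")


def _model(frame, a, b, c):
    return a * np.exp(-b * frame) + c


def fit_bleach(calibration_grays) -> BleachFit:
    """Nonlinear least-squares fit of a*exp(-b*frame)+c to the calibration grays.

    Initial guesses: c from the last-decile mean, a from the first-decile
    mean minus c, b from a log-linear fit of (gray - c).  On non-convergence
    a flagged flat fit (b=0, c=mean) is returned so the correction degrades
    to the identity; its R^2 will be low, which callers may warn about.
    """
    y = np.asarray(calibration_grays, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 calibration samples")
    frames = np.arange(y.size, dtype=float)

    dec = max(1, y.size // 10)
    c0 = float(y[-dec:].mean())
    a0 = float(y[:dec].mean()) - c0
    b0 = 0.0
    if a0 > 0:
        resid = y - c0
        mask = resid > 0.05 * a0
        if mask.sum() >= 2:
            slope = np.polyfit(frames[mask], np.log(resid[mask]), 1)[0]
            b0 = max(-slope, 0.0)
    if b0 == 0.0:
        b0 = 1.0 / max(y.size, 1)

    fallback = BleachFit(a=0.0, b=0.0, c=float(y.mean()), r_squared=_r2(y, np.full_like(y, y.mean())), converged=False)
    if a0 <= 0:
        # non-decaying input: flat profile, correction is the identity
        return fallback
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _model, frames, y, p0=(a0, b0, c0), maxfev=10000
            )
    except RuntimeError:
        return fallback
    a, b, c = (float(v) for v in popt)
    if not all(map(math.isfinite, (a, b, c))):
        return fallback
    return BleachFit(a=a, b=b, c=c, r_squared=_r2(y, _model(frames, a, b, c)))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    # R^2 = 1 - SSE/SSD (residual over total sum of squared deviations)
    ssd = float(((y - y.mean()) ** 2).sum())
    sse = float(((y - yhat) ** 2).sum())
    if ssd == 0.0:
        return 1.0 if sse == 0.0 else -math.inf
    return 1.0 - sse / ssd


def correct_frame(gray: float, frame: int, fit: BleachFit) -> float:
    """gray * offset(0)/offset(frame); the identity at frame 0 or for b=0."""
    denom = float(fit.offset(frame))
    if denom <= 0:
        raise ValueError("degenerate bleach fit: non-positive predicted offset")
    return gray * (fit.a + fit.c) / denom


def make_baseline(
    corrected_grays, calibration_frames: int, f0_window: int = 50
) -> BaselineState:
    """F0 from the mean of the first ``f0_window`` corrected calibration frames."""
    y = np.asarray(corrected_grays, dtype=float)
    window = min(f0_window, y.size)
    return BaselineState(
        f0=float(y[:window].mean()),
        calibration_frames=calibration_frames,
        f0_window=f0_window,
    )


def compute_dff(gray_corrected: float, baseline: BaselineState) -> float:
    """Bleach-corrected relative fluorescence change, in percent."""
    return (gray_corrected - baseline.f0) / baseline.f0 * 100.0
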