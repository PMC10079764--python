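"""Voltage-to-fluorescence sensor model: linear GEVI response, photobleaching,
shot noise and camera quantization.

Fluorescence scales linearly with membrane voltage (rhodopsin-based
indicators such as QuasAr2 are close to linear over the physiological
range).  The whole signal bleaches multiplicatively along a single
exponential-plus-offset profile; photon shot noise follows the Gaussian
approximation to Poisson counting, valid at the >=1e4 photons per frame of
all presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensorConfig",
    "FrameSample",
    "bleach_profile",
    "expected_photons",
    "sample_frame",
    "sensor_preset",
]


@dataclass
class SensorConfig:
    dff_per_mv: float  # % dF/F0 per mV
    reference_voltage: float  # mV giving dF/F0 = 0
    photons_per_frame: float  # unbleached count at the reference voltage
    bleach_a: float = 0.3  # exponential amplitude (arbitrary ADU-equivalents)
    bleach_b: float = 0.002  # per-frame decay rate
    bleach_c: float = 0.7  # offset
    adu_per_photon: float = 1.0
    exposure: float = 10.0  # ms
    frame_period: float = 10.0  # ms

    def __post_init__(self) -> None:
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be > 0")
        if self.frame_period < self.exposure:
            raise ValueError("frame_period must be >= exposure")
        if self.bleach_b < 0:
            raise ValueError("bleach_b must be >= 0")

    @property
    def fps(self) -> float:
        return 1000.0 / self.frame_period


@dataclass
class FrameSample:
    frame: int
    time: float  # ms, = frame * frame_period
    gray: float  # ADU, non-negative


def bleach_profile(frame: int | np.ndarray, config: SensorConfig):
    """a*exp(-b*frame) + c, normalized to 1 at frame 0."""
    raw = config.bleach_a * np.exp(-config.bleach_b * np.asarray(frame, float)) + config.bleach_c
    return raw / (config.bleach_a + config.bleach_c)


def expected_photons(voltage: float, frame: int, config: SensorConfig) -> float:
    """Mean photon count for one frame at the given membrane voltage."""
    rel = 1.0 + config.dff_per_mv * (voltage - config.reference_voltage) / 100.0
    n = config.photons_per_frame * rel * float(bleach_profile(frame, config))
    return max(n, 0.0)


def sample_frame(
    voltage: float,
    frame: int,
    config: SensorConfig,
    rng: np.random.Generator | None = None,
) -> FrameSample:
    """Draw one camera frame; shot noise SD = sqrt(N), quantized to integer ADU.

    With ``rng is None`` the noise-free expectation is returned.
    """
    n = expected_photons(voltage, frame, config)
    if rng is not None:
        n = rng.normal(n, math.sqrt(n)) if n > 0 else 0.0
    gray = round(max(n, 0.0) * config.adu_per_photon)
    return FrameSample(frame=frame, time=frame * config.frame_period, gray=float(gray))


def sensor_preset(name: str, photons_per_frame: float | None = None) -> SensorConfig:
    """Tissue-matched sensor configurations.

    The fluorescence-voltage slope differs per tissue (10% dF/F0 per 22 mV
    in body-wall muscle, per 65 mV in the DVB neuron, ~21% per 100 mV in
    hippocampal neurons); this reflects different fractions of indicator in
    the plasma membrane and is kept as an empirical constant per preset.
    """
    from .plant import PHYSIOLOGY, make_preset

    rest = make_preset(name).resting_potential
    if name == "dvb":
        slope = 10.0 / PHYSIOLOGY["dvb"]["mv_per_10pct_dff"]
        photons = 400_000.0
    elif name == "mammalian":
        slope = 0.21
        photons = 1_000_000.0
    elif name == "pharynx":
        slope = 10.0 / PHYSIOLOGY["bwm"]["mv_per_10pct_dff"]
        photons = 900_000.0
    else:  # bwm, unc13, egl19
        slope = 10.0 / PHYSIOLOGY["bwm"]["mv_per_10pct_dff"]
        photons = 1_800_000.0
    if photons_per_frame is not None:
        photons = photons_per_frame
    return SensorConfig(
        dff_per_mv=slope, reference_voltage=rest, photons_per_frame=photons
    )
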