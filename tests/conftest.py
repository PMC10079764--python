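from dataclasses import replace

import pytest

from ovclamp.control import IControllerConfig, controller_preset
from ovclamp.plant import make_preset
from ovclamp.sensor import sensor_preset


@pytest.fixture(scope="session")
def bwm_plant():
    return make_preset("bwm")


@pytest.fixture(scope="session")
def bwm_plant_quiet(bwm_plant):
    """Noise-free reference muscle for deterministic closed-loop checks."""
    return replace(bwm_plant, noise_sd=0.0)


@pytest.fixture(scope="session")
def bwm_sensor():
    return sensor_preset("bwm")


@pytest.fixture(scope="session")
def bwm_controller():
    return controller_preset("bwm")


@pytest.fixture(scope="session")
def fine_controller(bwm_controller):
    """Tighter tolerance variant used where the dead band would mask effects."""
    return IControllerConfig(
        ki=bwm_controller.ki,
        tolerance=0.25,
        start_wavelength=bwm_controller.start_wavelength,
    )
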