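import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from melstep.fixtures import (  # noqa: E402
    fixture_background,
    fixture_device,
    rod_control_background,
)


@pytest.fixture(scope="session")
def device():
    """In-vivo fixture device (lens-filtered sensitivities)."""
    return fixture_device(in_vivo=True)


@pytest.fixture(scope="session")
def device_vitro():
    return fixture_device(in_vivo=False)


@pytest.fixture(scope="session")
def background():
    return fixture_background()


@pytest.fixture(scope="session")
def rod_bg():
    """Blue background used for the melanopsin-silent rod-contrast controls."""
    return rod_control_background()


@pytest.fixture(scope="session")
def pair71(device, background):
    return device.solve_silent_step(background, "rod", "melanopsin", 0.71)


@pytest.fixture(scope="session")
def contrast_series(device, background):
    return device.contrast_series(
        background, [0.71, 0.60, 0.51, 0.38, 0.32, 0.21, 0.11]
    )


@pytest.fixture(scope="session")
def pair_at(device):
    def _pair_at(nd: float):
        return device.solve_silent_step(fixture_background(nd), "rod", "melanopsin", 0.71)

    return _pair_at


@pytest.fixture(scope="session")
def level_log(device):
    from melstep.spectra import log_flux

    def _level_log(nd: float) -> float:
        return log_flux(device.setting_flux(fixture_background(nd), "melanopsin"))

    return _level_log
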