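"""Canonical two-LED device fixture and study backgrounds.

Measured LED spectra for the original experiments are not published, so the
package ships a parametric stand-in (synthetic): Gaussian spectral power
densities peaking at 438 nm ("blue", the step primary) and 575 nm ("yellow",
the background primary). The default bandwidth is 18 nm FWHM, chosen so that
the fixture device can realise the full 71-11% melanopsin contrast series
while rod-silent (wider Gaussians leak too much of each band into the other
pigment and cap the achievable contrast just below 71%).

Unit normalisation: both primaries are scaled to deliver the same rod-opsin
effective photon flux at unit drive, so a rod-silent exchange of pure yellow
for pure blue conserves the drive sum; the absolute scale is set so that the
default background (yellow at half drive, ND0) delivers 10^14.3 melanopsin-
effective photons/cm^2/s, a bright "daylight" background.
"""

from __future__ import annotations

import numpy as np

from .spectra import (
    MELANOPSIN_LAMBDA_MAX,
    ROD_LAMBDA_MAX,
    Photopigment,
    SpectralFunction,
    default_grid,
    effective_photon_flux,
    gaussian_spd,
    lens_transmission,
    pigment_sensitivity,
)
from .substitution import Primary, StimulusDevice, StimulusSetting

__all__ = [
    "BLUE_PEAK_NM",
    "YELLOW_PEAK_NM",
    "FIXTURE_FWHM_NM",
    "BACKGROUND_LOG_MEL",
    "fixture_sensitivities",
    "fixture_device",
    "fixture_background",
]

BLUE_PEAK_NM = 438.0
YELLOW_PEAK_NM = 575.0
FIXTURE_FWHM_NM = 18.0
#: Melanopsin-effective log flux of the default background (yellow, w=0.5, ND0).
BACKGROUND_LOG_MEL = 14.3
BACKGROUND_YELLOW_WEIGHT = 0.5


def fixture_sensitivities(
    in_vivo: bool,
    grid: np.ndarray | None = None,
    rod_lambda_max: float = ROD_LAMBDA_MAX,
    mel_lambda_max: float = MELANOPSIN_LAMBDA_MAX,
) -> dict[str, SpectralFunction]:
    """Rod and melanopsin effective sensitivities (lens-filtered in vivo)."""
    grid = default_grid() if grid is None else grid
    lens = lens_transmission(grid) if in_vivo else None
    return {
        "rod": pigment_sensitivity(Photopigment("rod", rod_lambda_max, in_vivo), grid, lens),
        "melanopsin": pigment_sensitivity(
            Photopigment("melanopsin", mel_lambda_max, in_vivo), grid, lens
        ),
    }


def fixture_device(
    in_vivo: bool = True,
    fwhm_nm: float = FIXTURE_FWHM_NM,
    blue_gain: float = 1.0,
    grid: np.ndarray | None = None,
) -> StimulusDevice:
    """The standard blue/yellow Gaussian-LED device with unit headroom."""
    grid = default_grid() if grid is None else grid
    sens = fixture_sensitivities(in_vivo, grid)
    blue = gaussian_spd(BLUE_PEAK_NM, fwhm_nm, 1.0, grid)
    yellow = gaussian_spd(YELLOW_PEAK_NM, fwhm_nm, 1.0, grid)
    # equalise rod-effective flux at unit drive
    rod_b = effective_photon_flux(blue, sens["rod"]).flux
    rod_y = effective_photon_flux(yellow, sens["rod"]).flux
    blue = blue.scaled(rod_y / rod_b)
    # absolute scale: default background hits BACKGROUND_LOG_MEL
    mel_y = effective_photon_flux(yellow, sens["melanopsin"]).flux
    scale = 10.0**BACKGROUND_LOG_MEL / (BACKGROUND_YELLOW_WEIGHT * mel_y)
    blue = blue.scaled(scale)
    yellow = yellow.scaled(scale)
    return StimulusDevice(
        [Primary("blue", blue), Primary("yellow", yellow)], sens, blue_gain=blue_gain
    )


def fixture_background(nd: float = 0.0) -> StimulusSetting:
    """Default yellow background at half drive, optionally ND-attenuated."""
    return StimulusSetting({"yellow": BACKGROUND_YELLOW_WEIGHT}, nd=nd)


def rod_control_background(nd: float = 0.0) -> StimulusSetting:
    """Blue background for the rod-contrast control stimuli.

    The rod controls present melanopsin-isoluminant yellow flashes against a
    blue background; a yellow background has no blue drive to trade away, so
    positive rod contrasts are only reachable from a blue-rich background.
    """
    return StimulusSetting({"blue": 0.35}, nd=nd)
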