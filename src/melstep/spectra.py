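"""Spectra, photopigment templates and effective-photon-flux bookkeeping.

Everything downstream of a spectroradiometer measurement lives here: sampled
spectral functions on a common wavelength grid, the Govardovskii A1 visual
pigment nomogram, pre-receptoral (lens) filtering, pigment-effective photon
flux by quadrature, neutral-density attenuation and log-irradiance units.

Conventions
-----------
* Wavelengths are nanometres on a strictly increasing, uniformly spaced grid
  (default 300-780 nm at 1 nm, the usual spectroradiometer convention).
* Spectral power densities are photons cm^-2 s^-1 nm^-1; integrated fluxes are
  photons cm^-2 s^-1 and are usually quoted as log10 ("log photons/cm^2/s").
* Sensitivities and transmissions are dimensionless in [0, 1], peak-normalised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SpectralFunction",
    "Photopigment",
    "Irradiance",
    "DEFAULT_GRID",
    "default_grid",
    "ROD_LAMBDA_MAX",
    "MELANOPSIN_LAMBDA_MAX",
    "pigment_nomogram",
    "lens_transmission",
    "apply_prereceptoral_filter",
    "pigment_sensitivity",
    "gaussian_spd",
    "effective_photon_flux",
    "attenuate",
    "retinal_to_corneal",
    "log_flux",
]

Kind = Literal["power_density", "sensitivity", "transmission"]

#: Standard mouse pigment peak wavelengths (nm). Configurable everywhere they
#: are used; these are conventional literature values, not fitted quantities.
ROD_LAMBDA_MAX = 498.0
MELANOPSIN_LAMBDA_MAX = 480.0


def default_grid(start: float = 300.0, stop: float = 780.0, step: float = 1.0) -> np.ndarray:
    """Uniform wavelength grid in nm, inclusive of both endpoints."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


DEFAULT_GRID = default_grid()


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled function of wavelength on a fixed uniform grid.

    ``kind`` distinguishes power densities (non-negative, arbitrary scale)
    from sensitivities/transmissions (bounded in [0, 1]).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: Kind = "power_density"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with at least two points")
        dw = np.diff(wl)
        if np.any(dw <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(dw, dw[0], rtol=1e-9, atol=1e-9):
            raise ValueError("wavelength grid must be uniformly spaced")
        if vals.shape != wl.shape:
            raise ValueError("values and wavelengths must have the same shape")
        if np.any(vals < 0):
            raise ValueError(f"{self.kind} values must be non-negative")
        if self.kind in ("sensitivity", "transmission") and np.any(vals > 1 + 1e-12):
            raise ValueError(f"{self.kind} values must lie in [0, 1]")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def same_grid(self, other: "SpectralFunction") -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and bool(
            np.allclose(self.wavelengths, other.wavelengths)
        )

    def scaled(self, factor: float) -> "SpectralFunction":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, values=self.values * factor)

    def value_at(self, wavelength: float) -> float:
        """Value at the grid point nearest ``wavelength`` (no interpolation)."""
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.values[idx])


@dataclass(frozen=True)
class Photopigment:
    """A visual pigment identified by its peak wavelength.

    ``in_vivo`` marks that pre-receptoral (lens) filtering should be applied
    when building the sensitivity; in-vitro (isolated retina) estimates omit
    the correction.
    """

    name: str
    lambda_max: float
    in_vivo: bool = False


@dataclass(frozen=True)
class Irradiance:
    """A pigment-effective photon flux with its measurement frame."""

    pigment: str
    flux: float  # photons cm^-2 s^-1
    frame: Literal["corneal", "retinal"] = "corneal"

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("flux must be non-negative")


# --- Govardovskii et al. (2000) A1 visual pigment template ------------------
# Alpha band: S(x) = 1 / (exp[A(a-x)] + exp[B(b-x)] + exp[C(c-x)] + D) with
# x = lambda_max / lambda and a depending weakly on lambda_max; beta band is a
# Gaussian whose position and width scale linearly with lambda_max. Constants
# below are the published A1 values and are deliberately fixed in code.
_A1_A = 69.7
_A1_B = 28.0
_A1_C = -14.9
_A1_D = 0.674
_A1_b = 0.922
_A1_c = 1.104
_BETA_AMP = 0.26


def _a1_template(lambda_max: float, wavelengths: np.ndarray) -> np.ndarray:
    x = lambda_max / wavelengths
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(_A1_A * (a - x))
        + np.exp(_A1_B * (_A1_b - x))
        + np.exp(_A1_C * (_A1_c - x))
        + _A1_D
    )
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = _BETA_AMP * np.exp(-(((wavelengths - lm_beta) / b_beta) ** 2))
    return alpha + beta


def pigment_nomogram(lambda_max: float, grid: np.ndarray | None = None) -> SpectralFunction:
    """Peak-normalised A1 pigment absorbance template (alpha + beta bands).

    Parameters
    ----------
    lambda_max : float
        Pigment peak wavelength in nm. Must lie within the grid span.
    grid : ndarray, optional
        Wavelength grid (defaults to 300-780 nm at 1 nm).

    Returns
    -------
    SpectralFunction
        Sensitivity with value exactly 1 at the grid point nearest
        ``lambda_max`` and values in [0, 1] everywhere.
    """
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if not (wl[0] <= lambda_max <= wl[-1]):
        raise ValueError(f"lambda_max {lambda_max} nm outside grid span [{wl[0]}, {wl[-1]}]")
    s = _a1_template(lambda_max, wl)
    return SpectralFunction(wl, s / s.max(), kind="sensitivity")


def lens_transmission(
    grid: np.ndarray | None = None, cut_nm: float = 360.0, width_nm: float = 12.0
) -> SpectralFunction:
    """Built-in sigmoidal short-wavelength lens cut template.

    A logistic in wavelength, T = 1/(1+exp(-(lambda-cut)/width)): near-full
    transmission through the visible range with a soft UV cut. The parameters
    are documented defaults, replaceable by a measured two-column CSV.
    """
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    t = 1.0 / (1.0 + np.exp(-(wl - cut_nm) / width_nm))
    return SpectralFunction(wl, t, kind="transmission")


def apply_prereceptoral_filter(
    sensitivity: SpectralFunction, lens: SpectralFunction
) -> SpectralFunction:
    """Pointwise product of sensitivity and lens transmission, re-peak-normalised."""
    if sensitivity.kind != "sensitivity":
        raise ValueError("first argument must be a sensitivity")
    if not sensitivity.same_grid(lens):
        raise ValueError("sensitivity and lens must share a wavelength grid")
    prod = sensitivity.values * lens.values
    peak = prod.max()
    if peak <= 0:
        raise ValueError("filtered sensitivity is identically zero (degenerate lens)")
    return SpectralFunction(sensitivity.wavelengths, prod / peak, kind="sensitivity")


def pigment_sensitivity(
    pigment: Photopigment,
    grid: np.ndarray | None = None,
    lens: SpectralFunction | None = None,
) -> SpectralFunction:
    """Nomogram for ``pigment``, lens-filtered when the in_vivo flag is set."""
    sens = pigment_nomogram(pigment.lambda_max, grid)
    if pigment.in_vivo:
        if lens is None:
            lens = lens_transmission(sens.wavelengths)
        sens = apply_prereceptoral_filter(sens, lens)
    return sens


def gaussian_spd(
    peak_nm: float,
    fwhm_nm: float,
    total_flux: float,
    grid: np.ndarray | None = None,
) -> SpectralFunction:
    """Gaussian LED spectral power density with a given total photon flux.

    ``total_flux`` is the integral over the grid in photons cm^-2 s^-1.
    """
    wl = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    g = np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2)
    g *= total_flux / np.trapezoid(g, wl)
    return SpectralFunction(wl, g, kind="power_density")


def effective_photon_flux(
    spd: SpectralFunction,
    sens: SpectralFunction,
    pigment: str = "",
    frame: Literal["corneal", "retinal"] = "corneal",
) -> Irradiance:
    """Pigment-effective photon flux: trapezoidal integral of spd * sensitivity.

    Linear in the spectrum: scaling ``spd`` by k scales the flux by k.
    """
    if spd.kind != "power_density":
        raise ValueError("spd must be a power density")
    if not spd.same_grid(sens):
        raise ValueError("spd and sensitivity must share a wavelength grid")
    flux = float(np.trapezoid(spd.values * sens.values, spd.wavelengths))
    return Irradiance(pigment=pigment, flux=flux, frame=frame)


def attenuate(x, nd: float):
    """Attenuate by a neutral density: multiply by 10**(-nd).

    Accepts an Irradiance, a SpectralFunction or a bare flux. ND composes
    additively: attenuate(x, a + b) == attenuate(attenuate(x, a), b).
    """
    if nd < 0:
        raise ValueError("optical density must be non-negative")
    factor = 10.0 ** (-nd)
    if isinstance(x, Irradiance):
        return replace(x, flux=x.flux * factor)
    if isinstance(x, SpectralFunction):
        return x.scaled(factor)
    return x * factor


def retinal_to_corneal(irr: Irradiance, pupil_factor: float = 0.5) -> Irradiance:
    """Convert a retinal irradiance to the equivalent corneal irradiance.

    Multiplies by pupil area / retinal area; 0.5 for a fully dilated mouse
    pupil.
    """
    if irr.frame != "retinal":
        raise ValueError("irradiance is not in the retinal frame")
    return Irradiance(pigment=irr.pigment, flux=irr.flux * pupil_factor, frame="corneal")


def log_flux(x) -> float:
    """log10 photon flux of an Irradiance or bare flux; errors on zero flux."""
    flux = x.flux if isinstance(x, Irradiance) else float(x)
    if flux <= 0:
        raise ValueError("log flux undefined for non-positive flux")
    return math.log10(flux)
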