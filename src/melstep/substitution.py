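"""Receptor silent substitution with two LED primaries.

Given two primaries ("blue" step and "yellow" background LEDs) and the
effective sensitivities of two photopigments (rod opsin and melanopsin), this
module solves for stimulus pairs that deliver identical effective photon flux
to one pigment (the *silenced* pigment) while presenting a prescribed
Michelson contrast to the other (the *target* pigment).

With exactly two primaries the problem is a 2x2 linear system and is solved
in closed form; feasibility reduces to the drive weights staying inside the
gamut box [0, max_drive] per primary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import Irradiance, SpectralFunction, attenuate, effective_photon_flux, log_flux

__all__ = [
    "GamutError",
    "DegenerateSpectraError",
    "Primary",
    "StimulusSetting",
    "StimulusPair",
    "StimulusDevice",
    "michelson_contrast",
]

#: Silenced-pigment residual contrast guaranteed by the solver.
SILENCE_TOL = 1e-9
#: Achieved-vs-requested target contrast tolerance.
TARGET_TOL = 1e-6


class GamutError(ValueError):
    """A solution requires a drive weight outside [0, max_drive]."""


class DegenerateSpectraError(ValueError):
    """The primaries do not span the two pigments (singular flux matrix)."""


@dataclass(frozen=True)
class Primary:
    """An LED primary: its unit-drive spectrum and drive headroom."""

    name: str
    spd_unit: SpectralFunction
    max_drive: float = 1.0

    def __post_init__(self) -> None:
        if self.max_drive <= 0:
            raise ValueError("max_drive must be positive")


@dataclass(frozen=True)
class StimulusSetting:
    """Per-primary drive weights plus a neutral-density attenuation."""

    weights: Mapping[str, float]
    nd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", dict(self.weights))
        if self.nd < 0:
            raise ValueError("nd must be non-negative")
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative drive weight for primary {name!r}")

    def weight(self, name: str) -> float:
        return float(self.weights.get(name, 0.0))


@dataclass(frozen=True)
class StimulusPair:
    """A background/step pair with its per-pigment fluxes and contrasts."""

    background: StimulusSetting
    step: StimulusSetting
    fluxes: Mapping[str, tuple[Irradiance, Irradiance]]  # pigment -> (bg, step)
    contrasts: Mapping[str, float]
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "background": {"weights": dict(self.background.weights), "nd": self.background.nd},
            "step": {"weights": dict(self.step.weights), "nd": self.step.nd},
            "fluxes": {
                pig: {
                    "background": bg.flux,
                    "step": st.flux,
                    "background_log": log_flux(bg) if bg.flux > 0 else None,
                    "step_log": log_flux(st) if st.flux > 0 else None,
                }
                for pig, (bg, st) in self.fluxes.items()
            },
            "contrasts": dict(self.contrasts),
        }


def michelson_contrast(step_flux, bg_flux) -> float:
    """(step - background) / (step + background); antisymmetric, in [-1, 1]."""
    s = step_flux.flux if isinstance(step_flux, Irradiance) else float(step_flux)
    b = bg_flux.flux if isinstance(bg_flux, Irradiance) else float(bg_flux)
    if s < 0 or b < 0:
        raise ValueError("fluxes must be non-negative")
    if s + b == 0:
        raise ValueError("Michelson contrast undefined when both fluxes are zero")
    return (s - b) / (s + b)


class StimulusDevice:
    """Two registered primaries plus per-pigment effective sensitivities.

    Parameters
    ----------
    primaries : sequence of Primary
        Exactly two primaries (the supported hardware configuration).
    sensitivities : mapping
        Pigment name -> peak-normalised effective sensitivity on the same
        wavelength grid as the primary spectra.
    blue_gain : float
        Per-preparation empirical correction applied to the blue weight of
        the *step* after solving, mirroring the small online LED adjustments
        made to find effective isoluminance in a live preparation. Default
        1.0 (no correction); values within a few percent of 1 are typical.
    """

    def __init__(
        self,
        primaries: Sequence[Primary],
        sensitivities: Mapping[str, SpectralFunction],
        blue_gain: float = 1.0,
    ) -> None:
        if len(primaries) != 2:
            raise ValueError("exactly two primaries are supported")
        self.primaries = {p.name: p for p in primaries}
        self._order = [p.name for p in primaries]
        self.sensitivities = dict(sensitivities)
        self.blue_gain = float(blue_gain)
        # unit-drive flux matrix: pigment -> per-primary effective flux
        self._unit_flux: dict[str, np.ndarray] = {}
        for pig, sens in self.sensitivities.items():
            self._unit_flux[pig] = np.array(
                [
                    effective_photon_flux(self.primaries[name].spd_unit, sens, pig).flux
                    for name in self._order
                ]
            )

    # -- flux bookkeeping ---------------------------------------------------

    def unit_flux(self, pigment: str) -> np.ndarray:
        try:
            return self._unit_flux[pigment]
        except KeyError:
            raise KeyError(f"no sensitivity registered for pigment {pigment!r}") from None

    def _weight_vector(self, setting: StimulusSetting) -> np.ndarray:
        unknown = set(setting.weights) - set(self._order)
        if unknown:
            raise KeyError(f"unknown primaries in setting: {sorted(unknown)}")
        return np.array([setting.weight(name) for name in self._order])

    def setting_flux(self, setting: StimulusSetting, pigment: str) -> Irradiance:
        """Effective flux of a setting: sum of weighted unit fluxes, ND-attenuated."""
        w = self._weight_vector(setting)
        flux = float(self.unit_flux(pigment) @ w)
        return attenuate(Irradiance(pigment=pigment, flux=flux), setting.nd)

    # -- solver -------------------------------------------------------------

    def _check_gamut(self, w: np.ndarray, context: str) -> np.ndarray:
        tol = 1e-12
        for i, name in enumerate(self._order):
            lim = self.primaries[name].max_drive
            if w[i] < -tol * max(1.0, lim) or w[i] > lim * (1 + 1e-12):
                raise GamutError(
                    f"{context}: required drive {w[i]:.6g} for primary {name!r} "
                    f"outside gamut [0, {lim}]"
                )
        return np.clip(w, 0.0, [self.primaries[n].max_drive for n in self._order])

    def _pair_from_weights(
        self, background: StimulusSetting, w_step: np.ndarray, label: str = ""
    ) -> StimulusPair:
        step = StimulusSetting(dict(zip(self._order, map(float, w_step))), nd=background.nd)
        fluxes = {}
        contrasts = {}
        for pig in self.sensitivities:
            bg_f = self.setting_flux(background, pig)
            st_f = self.setting_flux(step, pig)
            fluxes[pig] = (bg_f, st_f)
            contrasts[pig] = michelson_contrast(st_f, bg_f)
        return StimulusPair(background, step, fluxes, contrasts, label=label)

    def solve_silent_step(
        self,
        background: StimulusSetting,
        silenced: str,
        target: str,
        target_contrast: float,
    ) -> StimulusPair:
        """Step weights silencing one pigment at a prescribed target contrast.

        Solves the 2x2 system
            flux_silenced(step) = flux_silenced(background)
            flux_target(step)   = flux_target(background) * (1 + c) / (1 - c)
        and verifies the solution lies inside the gamut. The returned pair
        satisfies |silenced contrast| <= 1e-9 and |achieved - c| <= 1e-6
        (with the default blue_gain of 1).
        """
        if not -1.0 < target_contrast < 1.0:
            raise ValueError("target contrast must lie in (-1, 1)")
        m_sil = self.unit_flux(silenced)
        m_tgt = self.unit_flux(target)
        mat = np.vstack([m_sil, m_tgt])
        if abs(np.linalg.det(mat)) <= 1e-12 * np.linalg.norm(m_sil) * np.linalg.norm(m_tgt):
            raise DegenerateSpectraError(
                "primary spectra are degenerate for this pigment pair"
            )
        w_bg = self._weight_vector(background)
        f_sil = float(m_sil @ w_bg)
        f_tgt = float(m_tgt @ w_bg)
        if f_sil <= 0 or f_tgt <= 0:
            raise ValueError("background must deliver positive flux to both pigments")
        ratio = (1.0 + target_contrast) / (1.0 - target_contrast)
        w = np.linalg.solve(mat, np.array([f_sil, f_tgt * ratio]))
        w = self._check_gamut(w, f"target contrast {target_contrast:.3g}")
        if self.blue_gain != 1.0 and "blue" in self._order:
            w = w.copy()
            w[self._order.index("blue")] *= self.blue_gain
            w = self._check_gamut(w, "blue-gain correction")
        return self._pair_from_weights(
            background, w, label=f"{target}_contrast={target_contrast:g}"
        )

    def max_silent_contrast(
        self, background: StimulusSetting, silenced: str, target: str
    ) -> float:
        """Largest feasible target contrast under the gamut constraints.

        The silenced-pigment constraint confines step weights to a line
        segment inside the gamut box; target flux is linear along it, so the
        maximum sits at a segment endpoint and is computed in closed form.
        """
        m_sil = self.unit_flux(silenced)
        m_tgt = self.unit_flux(target)
        w_bg = self._weight_vector(background)
        f_sil = float(m_sil @ w_bg)
        f_tgt = float(m_tgt @ w_bg)
        if f_tgt <= 0:
            return 0.0
        # direction along the isoluminance line
        d = np.array([-m_sil[1], m_sil[0]])
        if np.allclose(d, 0):
            return 0.0
        t_lo, t_hi = -np.inf, np.inf
        lims = np.array([self.primaries[n].max_drive for n in self._order])
        for i in range(2):
            if d[i] > 0:
                t_lo = max(t_lo, (0.0 - w_bg[i]) / d[i])
                t_hi = min(t_hi, (lims[i] - w_bg[i]) / d[i])
            elif d[i] < 0:
                t_lo = max(t_lo, (lims[i] - w_bg[i]) / d[i])
                t_hi = min(t_hi, (0.0 - w_bg[i]) / d[i])
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi < t_lo:
            return 0.0
        best = max(float(m_tgt @ (w_bg + t * d)) for t in (t_lo, t_hi))
        if best <= f_tgt:
            return 0.0
        return (best - f_tgt) / (best + f_tgt)

    def contrast_series(
        self,
        background: StimulusSetting,
        targets: Sequence[float],
        silenced: str = "rod",
        target: str = "melanopsin",
    ) -> list[StimulusPair]:
        """One silent pair per requested target contrast.

        Raises GamutError identifying the first infeasible member.
        """
        pairs = []
        for c in targets:
            try:
                pairs.append(self.solve_silent_step(background, silenced, target, c))
            except GamutError as exc:
                raise GamutError(f"contrast {c:g} infeasible: {exc}") from exc
        return pairs

    def rod_contrast_control(
        self, background: StimulusSetting, targets: Sequence[float]
    ) -> list[StimulusPair]:
        """Melanopsin-isoluminant pairs presenting prescribed rod contrasts."""
        return self.contrast_series(
            background, targets, silenced="melanopsin", target="rod"
        )
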