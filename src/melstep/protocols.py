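"""Stimulation protocols as explicit timestamped epoch lists.

A protocol is a gap-free tiling of time by epochs, each bound to a stimulus
setting (or, for ramps, a start/end pair interpolated in optical density).
Builders cover the experimental repertoire:

* ``build_protocol1`` - melanopsin-isolating steps against a steady bright
  background, pseudo-randomly interleaved across contrasts.
* ``build_protocol2`` - steps superimposed on a slow neutral-density ramp
  (0.5 ND per 200 s, 9 levels per direction, 4 min per half-log cycle).
* ``build_flicker`` - fast blue/yellow alternation used for online
  rod-isoluminance calibration (2 or 4 Hz).
* ``build_dark_pulses`` - blue pulses from darkness over a range of
  irradiances.
* ``build_rod_flash`` - dim rod-favouring yellow flashes at a fixed rate.

``render_trace`` converts a protocol into continuous per-pigment effective
photon-flux time series; ramps interpolate linearly in optical density
(log-linearly in flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .substitution import StimulusDevice, StimulusPair, StimulusSetting

__all__ = [
    "Epoch",
    "Protocol",
    "StimulusTrace",
    "build_protocol1",
    "build_protocol2",
    "build_flicker",
    "build_dark_pulses",
    "build_rod_flash",
    "render_trace",
]

DARK_SETTING = StimulusSetting({}, nd=0.0)


@dataclass(frozen=True)
class Epoch:
    kind: str  # adaptation | background | ramp | hold | step | flash | dark
    t_start: float
    duration: float
    setting_start: StimulusSetting
    setting_end: StimulusSetting
    label: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "t_start": self.t_start,
            "duration": self.duration,
            "setting_start": {"weights": dict(self.setting_start.weights), "nd": self.setting_start.nd},
            "setting_end": {"weights": dict(self.setting_end.weights), "nd": self.setting_end.nd},
            "label": self.label,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "Epoch":
        return Epoch(
            kind=d["kind"],
            t_start=float(d["t_start"]),
            duration=float(d["duration"]),
            setting_start=StimulusSetting(d["setting_start"]["weights"], d["setting_start"]["nd"]),
            setting_end=StimulusSetting(d["setting_end"]["weights"], d["setting_end"]["nd"]),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class Protocol:
    epochs: tuple[Epoch, ...]
    seed: int = 0
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        object.__setattr__(self, "metadata", dict(self.metadata))
        if not self.epochs:
            raise ValueError("protocol must contain at least one epoch")
        t = self.epochs[0].t_start
        for ep in self.epochs:
            if abs(ep.t_start - t) > 1e-9:
                raise ValueError("epochs must tile time without gaps or overlaps")
            t = ep.t_end

    @property
    def duration(self) -> float:
        return self.epochs[-1].t_end - self.epochs[0].t_start

    def epochs_of_kind(self, *kinds: str) -> list[Epoch]:
        return [ep for ep in self.epochs if ep.kind in kinds]

    def event_times(self, *kinds: str) -> np.ndarray:
        """Onset times of epochs of the given kinds (default: step/flash)."""
        if not kinds:
            kinds = ("step", "flash")
        return np.array([ep.t_start for ep in self.epochs_of_kind(*kinds)])

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "metadata": dict(self.metadata),
            "epochs": [ep.to_dict() for ep in self.epochs],
        }

    @staticmethod
    def from_dict(d: Mapping) -> "Protocol":
        return Protocol(
            epochs=tuple(Epoch.from_dict(e) for e in d["epochs"]),
            seed=int(d.get("seed", 0)),
            metadata=d.get("metadata", {}),
        )


def _tile(specs: Sequence[tuple], t0: float = 0.0) -> list[Epoch]:
    """Assign contiguous start times to (kind, duration, s_start, s_end, label)."""
    epochs = []
    t = t0
    for kind, dur, s_start, s_end, label in specs:
        epochs.append(Epoch(kind, t, dur, s_start, s_end, label))
        t += dur
    return epochs


def _const(kind: str, dur: float, setting: StimulusSetting, label: str = "") -> tuple:
    return (kind, dur, setting, setting, label)


def build_protocol1(
    pair_series: Sequence[StimulusPair],
    step_s: float = 30.0,
    isi_s: float = 210.0,
    repeats: int = 14,
    adaptation_s: float = 600.0,
    seed: int = 0,
    metadata: Mapping[str, str] | None = None,
) -> Protocol:
    """Steps at several contrasts interleaved pseudo-randomly on a steady background.

    The trial order is a seeded Fisher-Yates shuffle of the
    ``repeats x len(pair_series)`` block list; the same seed reproduces the
    same order bit-for-bit.
    """
    if not pair_series:
        raise ValueError("pair_series must not be empty")
    if repeats < 1 or step_s <= 0 or isi_s <= 0:
        raise ValueError("repeats must be >= 1 and durations positive")
    background = pair_series[0].background
    order = np.repeat(np.arange(len(pair_series)), repeats)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    specs = [_const("adaptation", adaptation_s, background, "adaptation")]
    for idx in order:
        pair = pair_series[idx]
        specs.append(_const("step", step_s, pair.step, pair.label))
        specs.append(_const("background", isi_s, background, "isi"))
    return Protocol(
        tuple(_tile(specs)),
        seed=seed,
        metadata={"protocol": "protocol1", **(metadata or {})},
    )


def build_protocol2(
    pair_at: Callable[[float], StimulusPair],
    start_nd: float = 4.0,
    nd_step: float = 0.5,
    ramp_s: float = 200.0,
    hold_s: float = 10.0,
    step_s: float = 30.0,
    adaptation_s: float = 240.0,
    nd_max: float = 4.0,
    metadata: Mapping[str, str] | None = None,
) -> Protocol:
    """Melanopsin steps at every half-log level of a slow irradiance ramp.

    Each ND level contributes one full cycle (ramp-or-steady 200 s, hold 10 s,
    step 30 s = 4 min); with 9 levels per direction the up+down schedule lasts
    72 min, flanked by 4-min adaptation epochs at the dimmest level. The
    ``start_nd`` argument (4 or 0) selects which arm runs first; the epoch
    multiset is identical either way.
    """
    n = nd_max / nd_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("ND range must be divisible by nd_step")
    if start_nd not in (0.0, nd_max):
        raise ValueError("start_nd must be one of the ND range endpoints")
    levels_up = [nd_max - i * nd_step for i in range(int(round(n)) + 1)]  # dim -> bright
    levels_down = levels_up[::-1]

    def arm(levels: Sequence[float], name: str) -> list[tuple]:
        specs = []
        prev_bg = None
        for i, nd in enumerate(levels):
            pair = pair_at(nd)
            bg = pair.background
            tag = f"nd={nd:g}|arm={name}"
            if i == 0:
                specs.append(_const("background", ramp_s, bg, tag))
            else:
                specs.append(("ramp", ramp_s, prev_bg, bg, tag))
            specs.append(_const("hold", hold_s, bg, tag))
            specs.append(_const("step", step_s, pair.step, tag))
            prev_bg = bg
        return specs

    dim_bg = pair_at(nd_max).background
    arms = (
        arm(levels_up, "up") + arm(levels_down, "down")
        if start_nd == nd_max
        else arm(levels_down, "down") + arm(levels_up, "up")
    )
    specs = (
        [_const("adaptation", adaptation_s, dim_bg, "adaptation")]
        + arms
        + [_const("adaptation", adaptation_s, dim_bg, "adaptation")]
    )
    return Protocol(
        tuple(_tile(specs)),
        seed=0,
        metadata={"protocol": "protocol2", "start_nd": f"{start_nd:g}", **(metadata or {})},
    )


def build_flicker(
    blue_ms: float,
    yellow_ms: float,
    n_cycles: int,
    pair: StimulusPair,
    nd: float = 3.0,
    metadata: Mapping[str, str] | None = None,
) -> Protocol:
    """Alternating blue flash / yellow background calibration flicker.

    Frequency is 1000 / (blue_ms + yellow_ms) Hz: 50/200 ms gives 4 Hz,
    100/400 ms gives 2 Hz.
    """
    if blue_ms <= 0 or yellow_ms <= 0 or n_cycles < 1:
        raise ValueError("durations must be positive and n_cycles >= 1")
    flash = replace(pair.step, nd=nd)
    bg = replace(pair.background, nd=nd)
    specs = []
    for _ in range(n_cycles):
        specs.append(_const("flash", blue_ms / 1000.0, flash, "flicker_flash"))
        specs.append(_const("background", yellow_ms / 1000.0, bg, "flicker_bg"))
    freq = 1000.0 / (blue_ms + yellow_ms)
    return Protocol(
        tuple(_tile(specs)),
        seed=0,
        metadata={"protocol": "flicker", "frequency_hz": f"{freq:g}", **(metadata or {})},
    )


def build_dark_pulses(
    irradiances_log: Sequence[float],
    pulse_s: float = 10.0,
    isi_range_s: tuple[float, float] = (50.0, 110.0),
    seed: int = 0,
    setting_for: Callable[[float], StimulusSetting] | None = None,
    metadata: Mapping[str, str] | None = None,
) -> Protocol:
    """Blue pulses from darkness over a range of irradiances.

    Inter-pulse darkness durations are drawn uniformly from ``isi_range_s``
    with the given seed.
    """
    lo, hi = isi_range_s
    if not lo <= hi:
        raise ValueError("isi bounds must be ordered")
    if setting_for is None:
        setting_for = lambda log_i: StimulusSetting({"blue": 1.0}, nd=0.0)  # noqa: E731
    rng = np.random.default_rng(seed)
    specs = []
    for log_i in irradiances_log:
        specs.append(_const("dark", float(rng.uniform(lo, hi)), DARK_SETTING, "dark"))
        specs.append(_const("flash", pulse_s, setting_for(log_i), f"log_flux={log_i:g}"))
    return Protocol(
        tuple(_tile(specs)),
        seed=seed,
        metadata={"protocol": "dark_pulses", **(metadata or {})},
    )


def build_rod_flash(
    flash_ms: float = 50.0,
    rate_hz: float = 1.0,
    n: int = 10,
    nd: float = 3.0,
    flash_setting: StimulusSetting | None = None,
    metadata: Mapping[str, str] | None = None,
) -> Protocol:
    """Dim rod-favouring yellow flashes (50 ms, ND3) at a fixed rate from dark."""
    period = 1.0 / rate_hz
    flash_s = flash_ms / 1000.0
    if flash_s >= period:
        raise ValueError("flash duration must be shorter than the period")
    if flash_setting is None:
        flash_setting = StimulusSetting({"yellow": 1.0}, nd=nd)
    else:
        flash_setting = replace(flash_setting, nd=nd)
    specs = []
    for _ in range(n):
        specs.append(_const("flash", flash_s, flash_setting, "rod_flash"))
        specs.append(_const("dark", period - flash_s, DARK_SETTING, "dark"))
    return Protocol(
        tuple(_tile(specs)), seed=0, metadata={"protocol": "rod_flash", **(metadata or {})}
    )


@dataclass(frozen=True)
class StimulusTrace:
    """Uniformly sampled per-pigment effective-flux time series."""

    times: np.ndarray
    dt: float
    fluxes: Mapping[str, np.ndarray]  # pigment -> photons cm^-2 s^-1
    nd: np.ndarray
    epoch_index: np.ndarray  # index into protocol.epochs per sample
    labels: tuple[str, ...]  # per-epoch labels
    kinds: tuple[str, ...]  # per-epoch kinds

    def __post_init__(self) -> None:
        n = self.times.size
        for pig, f in self.fluxes.items():
            if f.size != n:
                raise ValueError(f"flux series for {pig!r} has wrong length")
            if np.any(f < 0):
                raise ValueError("fluxes must be non-negative")


def render_trace(
    protocol: Protocol,
    dt: float,
    device: StimulusDevice,
    pigments: Sequence[str] = ("melanopsin", "rod"),
    suppress_kinds: Sequence[str] = (),
) -> StimulusTrace:
    """Sample a protocol into continuous per-pigment flux series.

    Ramps interpolate optical density linearly (exponentially in flux) and
    the drive weights linearly. With ``suppress_kinds`` the named epoch kinds
    are replaced by a continuation of the preceding epoch's end setting -
    used to render the "stimulus withheld" counterfactual of a protocol.
    """
    t0 = protocol.epochs[0].t_start
    n = int(round(protocol.duration / dt))
    times = t0 + dt * np.arange(n)
    starts = np.array([ep.t_start for ep in protocol.epochs])
    epoch_index = np.searchsorted(starts, times + 1e-12, side="right") - 1
    nd_arr = np.empty(n)
    flux = {pig: np.empty(n) for pig in pigments}
    unit = {pig: device.unit_flux(pig) for pig in pigments}

    prev_end: StimulusSetting | None = None
    for k, ep in enumerate(protocol.epochs):
        sel = epoch_index == k
        if not np.any(sel):
            prev_end = ep.setting_end
            continue
        s0, s1 = ep.setting_start, ep.setting_end
        if ep.kind in suppress_kinds and prev_end is not None:
            s0 = s1 = prev_end
        tt = times[sel]
        frac = (tt - ep.t_start) / ep.duration
        nd_t = s0.nd + (s1.nd - s0.nd) * frac
        nd_arr[sel] = nd_t
        w0 = np.array([s0.weight(name) for name in device._order])
        w1 = np.array([s1.weight(name) for name in device._order])
        for pig in pigments:
            base = float(unit[pig] @ w0) + frac * float(unit[pig] @ (w1 - w0))
            flux[pig][sel] = base * 10.0 ** (-nd_t)
        prev_end = ep.setting_end if ep.kind not in suppress_kinds else prev_end
    return StimulusTrace(
        times=times,
        dt=dt,
        fluxes=flux,
        nd=nd_arr,
        epoch_index=epoch_index,
        labels=tuple(ep.label for ep in protocol.epochs),
        kinds=tuple(ep.kind for ep in protocol.epochs),
    )
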