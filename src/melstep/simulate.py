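"""Synthetic retina / dLGN spike-train generator.

Produces spike datasets with the response structure the analysis stage
assumes, for preparations in which cones are absent:

* ``cnga3_retina`` / ``cnga3_dlgn`` - rods and melanopsin functional;
* ``rdcl_retina`` - melanopsin only, sluggish and unreliable;
* ``blockade`` - glutamatergic blockade: melanopsin only, slowed kinetics
  and reduced baseline firing.

Rate model (the package's own phenomenological construction)
-----------------------------------------------------------
Melanopsin pathway: a threshold-linear drive on log irradiance,
``d(t) = mel_gain * max(0, x(t) - theta(t))`` with ``x = log10`` melanopsin
flux, passed through an asymmetric first-order filter (time constant
``mel_tau_on_s`` rising, ``mel_tau_off_s`` falling). The adaptation state
``theta`` relaxes toward ``theta_base + adapt_gain * (xbar - theta_base)``
where ``xbar`` is an exponential running mean of the (floored) log flux with
time constant ``adapt_tau_s``; bright history therefore elevates the
effective threshold, and ``adapt_gain = 0`` freezes it at ``theta_base``.

Rod pathway: a transient contrast response. A running background estimate
``B`` tracks rod flux with time constant ``rod_tau_s``; the instantaneous
Michelson contrast ``(F - B)/(F + B)`` drives firing linearly in its
magnitude (``rod_gain`` Hz per unit |contrast|, so decrements evoke
OFF-type firing increases) whenever it exceeds
``rod_contrast_threshold``. Rod-silent stimuli keep the
rod flux constant, so this pathway is *exactly* zero for them.

Spiking: inhomogeneous Poisson by thinning of the (piecewise-constant)
rate, seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .protocols import Protocol, StimulusTrace, render_trace
from .substitution import StimulusDevice

__all__ = [
    "PREPS",
    "UnitParams",
    "PopulationSpec",
    "SpikeDataset",
    "make_unit_params",
    "apply_prep",
    "make_population",
    "mel_drive",
    "rod_drive",
    "unit_rate",
    "sample_spikes",
    "simulate_dataset",
]

PREPS = ("cnga3_retina", "cnga3_dlgn", "rdcl_retina", "blockade")
UNIT_CLASSES = ("mel_stepper", "irradiance_tracker", "rod_only", "null")

#: Simulation time step for rate traces (s).
DEFAULT_DT = 0.1
_LOG_FLOOR = 1e-30

#: Baseline scaling under synaptic blockade (documented calibration: the
#: recordings showed a significant drop in baseline firing under drug).
BLOCKADE_BASELINE_FACTOR = 0.5
#: dLGN steppers carry a light-adaptation gain that retinal units lack
#: (the threshold shift was seen in vivo only).
DLGN_ADAPT_GAIN = 0.6


@dataclass(frozen=True)
class UnitParams:
    """Ground-truth kinetic parameters of one simulated unit."""

    unit_class: str = "mel_stepper"
    prep: str = "cnga3_dlgn"
    baseline_hz: float = 5.0
    rod_gain: float = 20.0  # Hz per unit rod contrast
    rod_tau_s: float = 1.0
    rod_contrast_threshold: float = 0.10
    mel_gain: float = 2.0  # Hz per log unit above threshold
    mel_tau_on_s: float = 2.5
    mel_tau_off_s: float = 12.0
    mel_threshold_log: float = 12.0
    adapt_gain: float = 0.0  # in [0, 1]
    adapt_tau_s: float = 700.0
    reliability_p: float = 1.0
    rate_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit class {self.unit_class!r}")
        if self.prep not in PREPS:
            raise ValueError(f"unknown prep {self.prep!r}")
        for name in ("rod_tau_s", "mel_tau_on_s", "mel_tau_off_s", "adapt_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.reliability_p <= 1.0:
            raise ValueError("reliability_p must lie in [0, 1]")
        if not 0.0 <= self.adapt_gain <= 1.0:
            raise ValueError("adapt_gain must lie in [0, 1]")
        for name in ("baseline_hz", "rod_gain", "mel_gain", "rate_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Per-class parameter overrides (relative to UnitParams defaults).
CLASS_DEFAULTS: dict[str, dict] = {
    # responds to abrupt melanopsin steps; adapting threshold
    "mel_stepper": {"mel_gain": 2.0, "mel_tau_on_s": 2.5, "mel_tau_off_s": 12.0},
    # tracks slow background changes; very slow filter suppresses 30-s steps
    "irradiance_tracker": {
        "mel_gain": 1.5,
        "mel_tau_on_s": 300.0,
        "mel_tau_off_s": 300.0,
        "adapt_gain": 0.0,
    },
    "rod_only": {"mel_gain": 0.0, "rod_gain": 30.0},
    "null": {"mel_gain": 0.0, "rod_gain": 0.0},
}


def make_unit_params(unit_class: str, prep: str = "cnga3_dlgn", **overrides) -> UnitParams:
    """Class defaults for a preparation, before per-unit jitter."""
    kw: dict = {"unit_class": unit_class, "prep": "cnga3_dlgn"}
    kw.update(CLASS_DEFAULTS.get(unit_class, {}))
    if unit_class == "mel_stepper" and prep == "cnga3_dlgn":
        kw.setdefault("adapt_gain", DLGN_ADAPT_GAIN)
    kw.update(overrides)
    base = UnitParams(**kw)
    return apply_prep(base, prep)


def apply_prep(p: UnitParams, prep: str) -> UnitParams:
    """Transform cnga3 unit parameters into another preparation's regime.

    Idempotent: applying the same preparation twice equals applying it once.
    Cnga3 preparations are returned unchanged apart from the prep tag.
    """
    if prep not in PREPS:
        raise ValueError(f"unknown prep {prep!r}")
    if p.prep == prep:
        return p
    if prep == "blockade":
        return replace(
            p,
            prep=prep,
            rod_gain=0.0,
            baseline_hz=p.baseline_hz * BLOCKADE_BASELINE_FACTOR,
            mel_tau_on_s=7.5,
            mel_tau_off_s=38.0,
            adapt_gain=0.0,
        )
    if prep == "rdcl_retina":
        return replace(
            p,
            prep=prep,
            rod_gain=0.0,
            mel_tau_on_s=6.0,
            mel_tau_off_s=50.0,
            reliability_p=min(p.reliability_p, 0.6),
            adapt_gain=0.0,
        )
    if prep == "cnga3_retina":
        return replace(p, prep=prep, adapt_gain=0.0)
    return replace(p, prep=prep)  # cnga3_dlgn


@dataclass(frozen=True)
class PopulationSpec:
    """How many units of each response class to simulate, and with what jitter."""

    n_units: int = 100
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "mel_stepper": 0.28,
            "irradiance_tracker": 0.17,
            "rod_only": 0.35,
            "null": 0.20,
        }
    )
    prep: str = "cnga3_dlgn"
    seed: int = 0
    param_jitter: float = 0.1  # relative SD of multiplicative jitter

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_fractions", dict(self.class_fractions))
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative and sum to 1")
        if self.prep not in PREPS:
            raise ValueError(f"unknown prep {self.prep!r}")


def allocate_classes(spec: PopulationSpec) -> list[str]:
    """Deterministic largest-remainder allocation of units to classes."""
    items = sorted(spec.class_fractions.items())
    quotas = [(name, spec.n_units * frac) for name, frac in items]
    counts = {name: int(np.floor(q)) for name, q in quotas}
    short = spec.n_units - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda nq: (nq[1] - np.floor(nq[1]), nq[0]), reverse=True)
    for name, _ in by_remainder[:short]:
        counts[name] += 1
    labels: list[str] = []
    for name, _ in items:
        labels.extend([name] * counts[name])
    return labels


_JITTERED = ("baseline_hz", "rod_gain", "mel_gain", "mel_tau_on_s", "mel_tau_off_s")


def make_population(spec: PopulationSpec) -> list[UnitParams]:
    """Per-unit parameters: class defaults, prep transform, seeded jitter.

    Rate and kinetic parameters receive multiplicative Gaussian jitter
    (relative SD ``param_jitter``, floored at 0.2x); the melanopsin log
    threshold receives additive jitter with SD ``param_jitter`` log units.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB10]))
    units = []
    for cls in allocate_classes(spec):
        p = make_unit_params(cls, spec.prep)
        changes = {}
        for name in _JITTERED:
            val = getattr(p, name)
            if val > 0:
                changes[name] = val * max(0.2, 1.0 + spec.param_jitter * rng.standard_normal())
        changes["mel_threshold_log"] = p.mel_threshold_log + spec.param_jitter * rng.standard_normal()
        units.append(replace(p, **changes))
    return units


# ---------------------------------------------------------------------------
# rate engine (vectorised across units, sequential in time)
# ---------------------------------------------------------------------------


def _params_arrays(params: Sequence[UnitParams], dt: float) -> dict[str, np.ndarray]:
    def col(name):
        return np.array([getattr(p, name) for p in params])

    out = {name: col(name) for name in (
        "baseline_hz", "rod_gain", "rod_contrast_threshold", "mel_gain",
        "mel_threshold_log", "adapt_gain", "rate_floor",
    )}
    out["a_on"] = -np.expm1(-dt / col("mel_tau_on_s"))
    out["a_off"] = -np.expm1(-dt / col("mel_tau_off_s"))
    out["a_adapt"] = -np.expm1(-dt / col("adapt_tau_s"))
    out["a_rod"] = -np.expm1(-dt / col("rod_tau_s"))
    return out


def _population_rates(
    trace: StimulusTrace,
    trace_bg: StimulusTrace,
    params: Sequence[UnitParams],
    expr: np.ndarray,
) -> np.ndarray:
    """Firing-rate matrix (n_units x n_samples) for a unit population.

    ``expr`` is an (n_units x n_epochs) boolean mask: where False, the unit
    behaves as if the epoch's stimulus had been withheld (the flux series of
    ``trace_bg`` is substituted), implementing per-trial response reliability.
    """
    dt = trace.dt
    n_units = len(params)
    n = trace.times.size
    pa = _params_arrays(params, dt)

    x_on = np.log10(np.maximum(trace.fluxes["melanopsin"], _LOG_FLOOR))
    x_off = np.log10(np.maximum(trace_bg.fluxes["melanopsin"], _LOG_FLOOR))
    f_on = trace.fluxes["rod"]
    f_off = trace_bg.fluxes["rod"]
    e = trace.epoch_index
    same = (x_on == x_off) & (f_on == f_off)

    base = pa["baseline_hz"]
    g = pa["mel_gain"]
    thr = pa["mel_threshold_log"]
    again = pa["adapt_gain"]
    a_ad = pa["a_adapt"]
    a_on = pa["a_on"]
    a_off = pa["a_off"]
    rg = pa["rod_gain"]
    rthr = pa["rod_contrast_threshold"]
    a_rod = pa["a_rod"]
    floor = pa["rate_floor"]

    rate = np.empty((n_units, n), dtype=np.float32)
    all_true = np.ones(n_units, dtype=bool)

    # steady-state initialisation at the first sample
    m = all_true if same[0] else expr[:, e[0]]
    xs = np.where(m, x_on[0], x_off[0])
    xbar = np.maximum(xs, thr)
    theta = thr + again * (xbar - thr)
    r_mel = g * np.maximum(0.0, xs - theta)
    B = np.where(m, f_on[0], f_off[0]).astype(float)

    for t in range(n):
        if same[t]:
            xs = x_on[t]
            F = f_on[t]
        else:
            m = expr[:, e[t]]
            xs = np.where(m, x_on[t], x_off[t])
            F = np.where(m, f_on[t], f_off[t])
        xa = np.maximum(xs, thr)
        xbar += a_ad * (xa - xbar)
        theta = thr + again * (xbar - thr)
        draw = g * np.maximum(0.0, xs - theta)
        alpha = np.where(draw > r_mel, a_on, a_off)
        r_mel += alpha * (draw - r_mel)
        B += a_rod * (F - B)
        denom = F + B
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(denom > 0, (F - B) / denom, 0.0)
        rdrv = np.where(np.abs(c) >= rthr, rg * np.abs(c), 0.0)
        rate[:, t] = np.maximum(floor, base + r_mel + rdrv)
    return rate


def _single_unit_traces(trace: StimulusTrace, p: UnitParams):
    expr = np.ones((1, len(trace.labels)), dtype=bool)
    return _population_rates(trace, trace, [p], expr)[0]


def mel_drive(trace: StimulusTrace, p: UnitParams) -> np.ndarray:
    """Melanopsin-pathway drive (Hz above baseline) for one unit."""
    q = replace(p, rod_gain=0.0, baseline_hz=0.0, rate_floor=0.0)
    return _single_unit_traces(trace, q).astype(float)


def rod_drive(trace: StimulusTrace, p: UnitParams) -> np.ndarray:
    """Rod-pathway drive (Hz above baseline) for one unit."""
    q = replace(p, mel_gain=0.0, baseline_hz=0.0, rate_floor=0.0)
    return _single_unit_traces(trace, q).astype(float)


def unit_rate(trace: StimulusTrace, p: UnitParams) -> np.ndarray:
    """Total firing rate (baseline + both pathway drives, floored) for one unit."""
    return _single_unit_traces(trace, p).astype(float)


def sample_spikes(rate: np.ndarray, dt: float, seed, t0: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning a piecewise-constant rate.

    Counts in any window are Poisson with mean equal to the integrated rate;
    the same seed reproduces the identical train.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    rmax = float(rate.max(initial=0.0))
    if rmax <= 0:
        return np.empty(0)
    duration = rate.size * dt
    n_cand = rng.poisson(rmax * duration)
    tt = rng.uniform(0.0, duration, size=n_cand)
    u = rng.uniform(0.0, rmax, size=n_cand)
    keep = u < rate[np.minimum((tt / dt).astype(int), rate.size - 1)]
    return t0 + np.sort(tt[keep])


@dataclass
class SpikeDataset:
    """Per-unit, per-trial spike times with ground truth and protocol reference."""

    spikes: dict[int, dict[int, np.ndarray]]  # unit -> trial -> times (s)
    params: dict[int, UnitParams]
    protocol: Protocol

    @property
    def unit_ids(self) -> list[int]:
        return sorted(self.spikes)

    def trains(self, unit_id: int) -> dict[int, np.ndarray]:
        return self.spikes[unit_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uid in self.unit_ids:
            for trial, tt in sorted(self.spikes[uid].items()):
                rows.append(
                    pd.DataFrame(
                        {"unit_id": uid, "trial_id": trial, "spike_time_s": tt}
                    )
                )
        if not rows:
            return pd.DataFrame(columns=["unit_id", "trial_id", "spike_time_s"])
        return pd.concat(rows, ignore_index=True)

    @staticmethod
    def from_frame(
        df: pd.DataFrame, protocol: Protocol, params: Mapping[int, UnitParams] | None = None
    ) -> "SpikeDataset":
        spikes: dict[int, dict[int, np.ndarray]] = {}
        for (uid, trial), grp in df.groupby(["unit_id", "trial_id"]):
            spikes.setdefault(int(uid), {})[int(trial)] = np.sort(
                grp["spike_time_s"].to_numpy(dtype=float)
            )
        return SpikeDataset(spikes=spikes, params=dict(params or {}), protocol=protocol)


def simulate_dataset(
    protocol: Protocol,
    spec: PopulationSpec,
    device: StimulusDevice,
    n_repeats: int = 1,
    dt: float = DEFAULT_DT,
) -> SpikeDataset:
    """Simulate a unit population through a protocol.

    Each repeat replays the whole protocol with fresh reliability draws and
    spike noise. Per-trial response expression is Bernoulli(``reliability_p``)
    per step/flash epoch; non-expressed trials see the background
    continuation instead of the stimulus. Ground truth is stored alongside
    the spikes.
    """
    trace = render_trace(protocol, dt, device)
    trace_bg = render_trace(protocol, dt, device, suppress_kinds=("step", "flash"))
    params = make_population(spec)
    n_units = len(params)
    n_epochs = len(protocol.epochs)
    stim_epochs = np.array([k in ("step", "flash") for k in trace.kinds])
    rel = np.array([p.reliability_p for p in params])

    spikes: dict[int, dict[int, np.ndarray]] = {u: {} for u in range(n_units)}
    for trial in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED, trial]))
        expr = np.ones((n_units, n_epochs), dtype=bool)
        if np.any(rel < 1.0) and np.any(stim_epochs):
            draws = rng.random((n_units, int(stim_epochs.sum()))) < rel[:, None]
            expr[:, stim_epochs] = draws
        rate = _population_rates(trace, trace_bg, params, expr)
        t0 = float(trace.times[0])
        for u in range(n_units):
            spikes[u][trial] = sample_spikes(
                rate[u], dt, np.random.SeedSequence([spec.seed, 0x5EED, trial, u]), t0=t0
            )
    return SpikeDataset(spikes=spikes, params=dict(enumerate(params)), protocol=protocol)
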