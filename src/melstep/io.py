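"""File formats: spectra CSV, protocol JSON, spike datasets, result tables.

All artefacts are plain text. Spectra are two-column CSV (wavelength_nm,
value) with a header row; protocols serialise to JSON; spike datasets are
long-format CSV (unit_id, trial_id, spike_time_s) with a ground-truth JSON
sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import Protocol
from .simulate import SpikeDataset, UnitParams
from .spectra import SpectralFunction
from .substitution import StimulusPair

__all__ = [
    "FormatError",
    "load_spd",
    "save_spectrum",
    "save_protocol",
    "load_protocol",
    "save_pairs",
    "save_dataset",
    "load_dataset",
]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


def load_spd(
    path, grid: np.ndarray | None = None, kind: str = "power_density"
) -> SpectralFunction:
    """Load a two-column (wavelength_nm, value) CSV spectrum.

    A header row is required. When ``grid`` is given the spectrum is
    regridded by linear interpolation (zero outside the measured span),
    which preserves total photon counts to well under 0.1% for smooth
    spectra measured on a comparable or finer grid.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (wavelength_nm, value)")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    for arr, what in ((wl, "wavelength"), (vals, "value")):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise FormatError(f"{path}: non-numeric {what} at data row {bad[0] + 1}")
    dw = np.diff(wl)
    if np.any(dw <= 0):
        row = int(np.flatnonzero(dw <= 0)[0]) + 2
        raise FormatError(f"{path}: wavelengths not strictly increasing at data row {row}")
    neg = np.flatnonzero(vals < 0)
    if neg.size:
        raise FormatError(f"{path}: negative value at data row {neg[0] + 1}")
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        vals = np.interp(grid, wl, vals, left=0.0, right=0.0)
        wl = grid
    return SpectralFunction(wl, vals, kind=kind)


def save_spectrum(spec: SpectralFunction, path) -> None:
    pd.DataFrame({"wavelength_nm": spec.wavelengths, "value": spec.values}).to_csv(
        path, index=False
    )


def save_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=1, sort_keys=True))


def load_protocol(path) -> Protocol:
    return Protocol.from_dict(json.loads(Path(path).read_text()))


def save_pairs(pairs: list[StimulusPair], path) -> None:
    Path(path).write_text(json.dumps([p.to_dict() for p in pairs], indent=1, sort_keys=True))


def save_dataset(dataset: SpikeDataset, csv_path, truth_path=None) -> None:
    dataset.to_frame().to_csv(csv_path, index=False, float_format="%.4f")
    if truth_path is not None:
        truth = {
            str(uid): dataclasses.asdict(p) for uid, p in sorted(dataset.params.items())
        }
        Path(truth_path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def load_dataset(csv_path, protocol: Protocol, truth_path=None) -> SpikeDataset:
    df = pd.read_csv(csv_path)
    required = {"unit_id", "trial_id", "spike_time_s"}
    if not required.issubset(df.columns):
        raise FormatError(f"{csv_path}: missing columns {sorted(required - set(df.columns))}")
    params = {}
    if truth_path is not None:
        raw = json.loads(Path(truth_path).read_text())
        params = {int(uid): UnitParams(**kw) for uid, kw in raw.items()}
    return SpikeDataset.from_frame(df, protocol, params)
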