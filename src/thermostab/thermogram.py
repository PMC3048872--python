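"""Containers and plain-text IO for scan data.

A thermogram is a heat-capacity trace on a strictly increasing temperature
grid plus the acquisition metadata needed to normalise it (scan rate,
loading concentration, calorimeter cell volume).  The ``stage`` field
tracks how far along the processing pipeline the trace is:

    raw -> reference_subtracted -> molar -> excess

and may only move forward.  Molar and excess values are in cal/(mol K).

The on-disk format is deliberately simple: ``#``-prefixed ``key=value``
header lines followed by two whitespace- or comma-delimited numeric
columns, temperature in degC first.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import celsius_to_kelvin, kelvin_to_celsius

STAGES = ("raw", "reference_subtracted", "molar", "excess")


class IncompatibleGridsError(ValueError):
    """Temperature ranges of two scans do not overlap."""


class MissingMetadataError(ValueError):
    """A processing step needs metadata the thermogram does not carry."""


def _validate_grid(temperature_k, values):
    t = np.asarray(temperature_k, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("temperature and values must be 1-D arrays of equal length")
    if t.size < 2:
        raise ValueError("a thermogram needs at least two points")
    if not np.all(np.diff(t) > 0):
        raise ValueError("temperature grid must be strictly increasing")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("temperatures and values must be finite")
    return t, v


@dataclass(frozen=True)
class Thermogram:
    """One calorimetric scan.

    Parameters
    ----------
    temperature_k : ndarray
        Strictly increasing grid, kelvin.
    values : ndarray
        Heat capacity per grid point.  Instrument units before molar
        normalisation, cal/(mol K) afterwards.
    scan_rate_k_per_min : float or None
        Heating rate (metadata only; an equilibrium analysis never uses it).
    protein_conc_molar : float or None
    cell_volume_l : float or None
    stage : str
        One of ``raw``, ``reference_subtracted``, ``molar``, ``excess``.
    """

    temperature_k: np.ndarray
    values: np.ndarray
    scan_rate_k_per_min: float | None = None
    protein_conc_molar: float | None = None
    cell_volume_l: float | None = None
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t, v = _validate_grid(self.temperature_k, self.values)
        object.__setattr__(self, "temperature_k", t)
        object.__setattr__(self, "values", v)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def temperature_c(self) -> np.ndarray:
        return kelvin_to_celsius(self.temperature_k)

    def with_values(self, values, stage: str | None = None) -> "Thermogram":
        """Copy with new values and (optionally) an advanced stage."""
        new_stage = self.stage if stage is None else stage
        if STAGES.index(new_stage) < STAGES.index(self.stage):
            raise ValueError(
                f"stage may only advance ({self.stage!r} -> {new_stage!r} is backwards)"
            )
        return replace(self, values=np.asarray(values, dtype=float), stage=new_stage)


@dataclass(frozen=True)
class MeltCurve:
    """Single-wavelength spectroscopic melt: signal vs temperature."""

    temperature_k: np.ndarray
    signal: np.ndarray
    wavelength_nm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t, v = _validate_grid(self.temperature_k, self.signal)
        object.__setattr__(self, "temperature_k", t)
        object.__setattr__(self, "signal", v)

    @property
    def temperature_c(self) -> np.ndarray:
        return kelvin_to_celsius(self.temperature_k)


@dataclass(frozen=True)
class TitrationSeries:
    """(ligand concentration, melting temperature) pairs."""

    conc_molar: np.ndarray
    tm_k: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.conc_molar, dtype=float)
        t = np.asarray(self.tm_k, dtype=float)
        if c.shape != t.shape or c.ndim != 1:
            raise ValueError("conc and tm must be 1-D arrays of equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "conc_molar", c)
        object.__setattr__(self, "tm_k", t)


# ---------------------------------------------------------------------------
# text IO

_FLOAT_KEYS = {
    "scan_rate_K_per_min": "scan_rate_k_per_min",
    "conc_molar": "protein_conc_molar",
    "cell_volume_L": "cell_volume_l",
}


def _parse_header_and_columns(text: str):
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"expected two numeric columns, got line {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError("no data rows found")
    arr = np.asarray(rows, dtype=float)
    return meta, arr[:, 0], arr[:, 1]


def read_thermogram(path_or_text) -> Thermogram:
    """Read a thermogram from the delimited text dialect.

    Accepts a path or a file-like/str payload.  Temperatures on disk are
    degC; metadata rides in ``# key=value`` header lines.
    """
    text = _slurp(path_or_text)
    meta, t_c, values = _parse_header_and_columns(text)
    kwargs = {}
    for disk_key, attr in _FLOAT_KEYS.items():
        if disk_key in meta:
            kwargs[attr] = float(meta.pop(disk_key))
    stage = meta.pop("stage", "raw")
    return Thermogram(
        temperature_k=celsius_to_kelvin(t_c),
        values=values,
        stage=stage,
        meta=meta,
        **kwargs,
    )


def write_thermogram(tg: Thermogram, path) -> None:
    lines = []
    for disk_key, attr in _FLOAT_KEYS.items():
        val = getattr(tg, attr)
        if val is not None:
            lines.append(f"# {disk_key}={val:.10g}")
    lines.append(f"# stage={tg.stage}")
    for key, val in tg.meta.items():
        lines.append(f"# {key}={val}")
    for t_c, v in zip(tg.temperature_c, tg.values):
        lines.append(f"{t_c:.6f}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_melt_curve(path_or_text) -> MeltCurve:
    text = _slurp(path_or_text)
    meta, t_c, signal = _parse_header_and_columns(text)
    wl = float(meta.pop("wavelength_nm")) if "wavelength_nm" in meta else None
    return MeltCurve(celsius_to_kelvin(t_c), signal, wavelength_nm=wl, meta=meta)


def write_melt_curve(mc: MeltCurve, path) -> None:
    lines = []
    if mc.wavelength_nm is not None:
        lines.append(f"# wavelength_nm={mc.wavelength_nm:.10g}")
    for key, val in mc.meta.items():
        lines.append(f"# {key}={val}")
    for t_c, v in zip(mc.temperature_c, mc.signal):
        lines.append(f"{t_c:.6f}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_titration(path_or_text) -> TitrationSeries:
    """Two columns: ligand concentration (mol/L), Tm (degC)."""
    text = _slurp(path_or_text)
    meta, conc, tm_c = _parse_header_and_columns(text)
    return TitrationSeries(conc, celsius_to_kelvin(tm_c), meta=meta)


def write_titration(ts: TitrationSeries, path) -> None:
    lines = [f"# {key}={val}" for key, val in ts.meta.items()]
    for c, t in zip(ts.conc_molar, kelvin_to_celsius(ts.tm_k)):
        lines.append(f"{c:.10g}\t{t:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _slurp(path_or_text) -> str:
    if isinstance(path_or_text, io.IOBase):
        return path_or_text.read()
    if isinstance(path_or_text, Path):
        return path_or_text.read_text()
    if isinstance(path_or_text, str):
        if "\n" in path_or_text or path_or_text.strip().startswith("#"):
            return path_or_text
        p = Path(path_or_text)
        if p.exists():
            return p.read_text()
        return path_or_text
    raise TypeError(f"cannot read thermogram from {type(path_or_text)}")
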