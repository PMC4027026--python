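"""1D spectrum and tabular-series containers plus plain-text I/O.

Spectra are stored as two-column (abscissa, intensity) text — whitespace- or
comma-separated — with ``# key: value`` header comments carrying units and
metadata.  The axis is always held ascending in memory; files written by
instruments in descending order are re-sorted on read and the original
orientation recorded in ``metadata['original_order']``.  Units are explicit
metadata and never inferred from magnitudes.

Series (temperature scans, titrations) travel as CSV with a header row whose
column names carry the units, e.g. ``T_K,CSA_ppm``.
"""
from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    AxisError,
    ParseError,
    SizeError,
    UnitConversionError,
    UnitError,
)

VALID_UNITS = ("kHz", "Hz", "ppm", "Gauss")
VALID_MODES = ("2H", "31P", "ESR-derivative", "1H")

_MIN_POINTS = 16


@dataclass
class Spectrum1D:
    """A sampled 1D spectrum with an ascending abscissa.

    Parameters
    ----------
    axis : ndarray
        Strictly increasing abscissa values (kHz, Hz, ppm or Gauss).
    intensity : ndarray
        Real intensities, same length as ``axis`` (>= 16 points).
    unit : str
        Axis unit, one of ``kHz | Hz | ppm | Gauss``.
    mode : str
        Nucleus or detection mode: ``2H | 31P | ESR-derivative | 1H``.
    temperature : float, optional
        Sample temperature in Kelvin.
    metadata : dict
        Free-form key/value pairs, round-tripped through file headers.
    """

    axis: np.ndarray
    intensity: np.ndarray
    unit: str
    mode: str
    temperature: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise AxisError("axis and intensity must be one-dimensional")
        if self.axis.size != self.intensity.size:
            raise SizeError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) "
                "differ in length"
            )
        if self.axis.size < _MIN_POINTS:
            raise SizeError(
                f"spectrum has {self.axis.size} points; at least {_MIN_POINTS} required"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise AxisError("axis must be strictly increasing")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown axis unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.mode not in VALID_MODES:
            raise UnitError(f"unknown mode {self.mode!r}; expected one of {VALID_MODES}")

    # -- convenience -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.axis.size)

    @property
    def step(self) -> float:
        """Median axis increment (axes are usually uniform)."""
        return float(np.median(np.diff(self.axis)))

    def replace(self, **kwargs) -> "Spectrum1D":
        """Return a copy with selected fields replaced."""
        data = dict(
            axis=self.axis.copy(),
            intensity=self.intensity.copy(),
            unit=self.unit,
            mode=self.mode,
            temperature=self.temperature,
            metadata=dict(self.metadata),
        )
        data.update(kwargs)
        return Spectrum1D(**data)


def _parse_header_line(line: str, metadata: dict) -> None:
    body = line.lstrip("#").strip()
    if ":" in body:
        key, _, value = body.partition(":")
        metadata[key.strip()] = value.strip()


def read_spectrum(
    path,
    dialect: str = "two-column",
    unit: str | None = None,
    mode: str | None = None,
) -> Spectrum1D:
    """Read a two-column or CSV spectrum file.

    ``unit`` / ``mode`` override header values when given; one of the two
    sources must provide each.  The axis is sorted ascending; duplicated
    abscissa values raise :class:`AxisError`.
    """
    if dialect not in ("two-column", "csv"):
        raise ParseError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else None
    metadata: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_header_line(line, metadata)
                continue
            fields = line.split(sep)
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                xs.append(float(fields[0]))
                ys.append(float(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric value") from exc
    if len(xs) < _MIN_POINTS:
        raise SizeError(f"{path}: only {len(xs)} data rows; at least {_MIN_POINTS} required")
    axis = np.asarray(xs)
    intensity = np.asarray(ys)
    order = np.argsort(axis, kind="stable")
    descending = bool(np.all(np.diff(axis) < 0))
    axis = axis[order]
    intensity = intensity[order]
    if np.any(np.diff(axis) <= 0):
        raise AxisError(f"{path}: axis not strictly monotonic after sorting")
    unit = unit or metadata.pop("unit", None)
    mode = mode or metadata.pop("mode", None)
    if unit is None or mode is None:
        raise UnitError(f"{path}: axis unit and mode must come from header or arguments")
    temperature = metadata.pop("temperature_K", None)
    if temperature is not None:
        temperature = float(temperature)
    metadata.setdefault("source_path", str(path))
    metadata["original_order"] = "descending" if descending else "ascending"
    return Spectrum1D(axis, intensity, unit=unit, mode=mode,
                      temperature=temperature, metadata=metadata)


def write_spectrum(s: Spectrum1D, path, dialect: str = "two-column") -> None:
    """Write a spectrum losslessly (12 significant digits) with its metadata."""
    if dialect not in ("two-column", "csv"):
        raise ParseError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "csv" else " "
    buf = io.StringIO()
    buf.write(f"# unit: {s.unit}\n")
    buf.write(f"# mode: {s.mode}\n")
    if s.temperature is not None:
        buf.write(f"# temperature_K: {s.temperature:.6g}\n")
    for key, value in s.metadata.items():
        if key in ("source_path",):
            continue
        buf.write(f"# {key}: {value}\n")
    for x, y in zip(s.axis, s.intensity):
        buf.write(f"{x:.12g}{sep}{y:.12g}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def convert_axis(
    s: Spectrum1D,
    target_unit: str,
    reference_frequency: float | None = None,
) -> Spectrum1D:
    """Convert the abscissa between ppm, Hz and kHz.

    ``reference_frequency`` is the spectrometer frequency in MHz and is
    required for ppm <-> frequency conversions (1 ppm at f MHz = f Hz).
    Gauss axes (ESR field sweeps) never convert.
    """
    if target_unit not in VALID_UNITS:
        raise UnitError(f"unknown target unit {target_unit!r}")
    if s.unit == target_unit:
        return s.replace()
    if s.unit == "Gauss" or target_unit == "Gauss":
        raise UnitConversionError("Gauss field axes do not convert to frequency units")
    # express current axis in Hz first
    if s.unit == "Hz":
        hz = s.axis
    elif s.unit == "kHz":
        hz = s.axis * 1e3
    else:  # ppm
        if reference_frequency is None:
            raise UnitConversionError("ppm conversion requires reference_frequency (MHz)")
        hz = s.axis * reference_frequency
    if target_unit == "Hz":
        new = hz
    elif target_unit == "kHz":
        new = hz / 1e3
    else:  # ppm
        if reference_frequency is None:
            raise UnitConversionError("ppm conversion requires reference_frequency (MHz)")
        new = hz / reference_frequency
    out = s.replace(axis=new, unit=target_unit)
    out.metadata["converted_from"] = s.unit
    return out


class SeriesTable:
    """A keyed table: strictly monotonic key column plus observable columns.

    Thin validation wrapper around a :class:`pandas.DataFrame`; column names
    carry units by convention (``T_K``, ``CSA_ppm``, ``F``, ``shift_H1_ppm``).
    """

    def __init__(self, df: pd.DataFrame, key: str | None = None):
        if df.shape[1] < 2:
            raise SizeError("SeriesTable needs a key column and at least one observable")
        self.key = key or df.columns[0]
        if self.key not in df.columns:
            raise AxisError(f"key column {self.key!r} not in table")
        kv = df[self.key].to_numpy(dtype=float)
        d = np.diff(kv)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise AxisError(f"key column {self.key!r} must be strictly monotonic")
        if np.all(d < 0):
            df = df.iloc[::-1].reset_index(drop=True)
        if df.drop(columns=[self.key]).isna().any().any():
            raise ParseError("SeriesTable observable columns contain missing values")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def key_values(self) -> np.ndarray:
        return self.df[self.key].to_numpy(dtype=float)

    def observable(self, column: str | None = None) -> np.ndarray:
        """Return one observable column (default: the first non-key column)."""
        if column is None:
            column = next(c for c in self.df.columns if c != self.key)
        return self.df[column].to_numpy(dtype=float)

    @classmethod
    def from_columns(cls, key: str, key_values, **observables) -> "SeriesTable":
        data = {key: np.asarray(key_values, dtype=float)}
        for name, vals in observables.items():
            data[name] = np.asarray(vals, dtype=float)
        return cls(pd.DataFrame(data), key=key)


def read_series(path, key: str | None = None) -> SeriesTable:
    """Read a SeriesTable CSV (header row names the units, '#' lines ignored)."""
    df = pd.read_csv(path, comment="#")
    return SeriesTable(df, key=key)


def write_series(table: SeriesTable, path, header_comments: Mapping | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_comments or {}).items():
            fh.write(f"# {k}: {v}\n")
        table.df.to_csv(fh, index=False, float_format="%.12g")
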