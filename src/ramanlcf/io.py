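"""Delimited-text I/O and run configuration.

Raman spectra are exchanged as two-column delimited text (wavenumber in
cm^-1, intensity in arbitrary units) with optional ``#`` comment lines;
peak tables as CSV with a header row ``component,frequency_cm1,intensity``
plus an optional ``label`` column.  All floats are written with 12
significant digits so repeated runs are byte-identical.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ParseError
from .lcf import BasisMatrix
from .spectral_model import (
    ComponentPeakTable,
    Spectrum,
    VibrationalMode,
    WavenumberGrid,
)

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_peak_table",
    "write_peak_table",
    "read_basis",
    "write_basis",
    "RunConfig",
    "load_config",
]

_FLOAT_FMT = "%.12g"
_SPLIT = re.compile(r"[,\t;]|\s+")


def read_spectrum(path) -> Spectrum:
    """Parse a two-column delimited text spectrum.

    Accepts comma, semicolon, tab or whitespace delimiters and ``#``
    comment/blank lines.  Descending (reversed instrument order) files are
    flipped so wavenumbers are always ascending in memory; duplicate or
    otherwise non-monotone wavenumbers are rejected.
    """
    path = Path(path)
    wavenumbers, intensities = [], []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _SPLIT.split(line) if f]
            if len(fields) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected 2 columns, got {line!r}")
            try:
                w, v = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric value in {line!r}"
                ) from None
            wavenumbers.append(w)
            intensities.append(v)
    if len(wavenumbers) < 2:
        raise FormatError(f"{path.name}: fewer than 2 data rows")
    w = np.asarray(wavenumbers)
    v = np.asarray(intensities)
    if np.all(np.diff(w) < 0):  # reversed instrument order
        w, v = w[::-1], v[::-1]
    if not np.all(np.diff(w) > 0):
        raise FormatError(
            f"{path.name}: wavenumbers are not strictly monotone "
            "(duplicate or shuffled rows?)"
        )
    return Spectrum(WavenumberGrid(w), v)


def write_spectrum(spectrum: Spectrum, path, *, header: str | None = None) -> None:
    """Write a spectrum as two-column CSV with an optional ``#`` header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# wavenumber_cm1,intensity\n")
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for w, v in zip(spectrum.grid.points, spectrum.values):
            fh.write(f"{_FLOAT_FMT % w},{_FLOAT_FMT % v}\n")


_REQUIRED_PEAK_COLS = ("component", "frequency_cm1", "intensity")


def read_peak_table(path) -> list[ComponentPeakTable]:
    """Read a peak-table CSV into per-component tables.

    Required columns: component, frequency_cm1, intensity; optional label
    and fwhm (per-component broadening override, must be constant within a
    component).  Rows are grouped by component in order of first
    appearance; duplicate (component, frequency) rows and negative
    intensities are rejected with the offending row named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path.name}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _REQUIRED_PEAK_COLS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)} (header row required)"
        )
    for col in ("frequency_cm1", "intensity"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path.name}: non-numeric {col} in data row {int(bad[0]) + 1}"
            )
        df[col] = pd.to_numeric(df[col])
    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise FormatError(
            f"{path.name}: negative intensity in data row {int(neg[0]) + 1}"
        )
    dup = df.duplicated(subset=["component", "frequency_cm1"])
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise FormatError(
            f"{path.name}: duplicate (component, frequency) in data row {row}"
        )
    tables = []
    for name in df["component"].drop_duplicates():
        sub = df[df["component"] == name]
        modes = tuple(
            VibrationalMode(
                float(r.frequency_cm1),
                float(r.intensity),
                str(getattr(r, "label", "") or "")
                if "label" in df.columns and pd.notna(getattr(r, "label", None))
                else "",
            )
            for r in sub.itertuples()
        )
        fwhm = None
        if "fwhm" in df.columns:
            vals = sub["fwhm"].dropna().unique()
            if len(vals) > 1:
                raise FormatError(
                    f"{path.name}: component {name!r} has conflicting fwhm values"
                )
            if len(vals) == 1:
                fwhm = float(vals[0])
        tables.append(ComponentPeakTable(str(name), modes, default_fwhm=fwhm))
    return tables


def write_peak_table(tables: list[ComponentPeakTable], path) -> None:
    path = Path(path)
    rows = []
    for t in tables:
        for m in t.modes:
            rows.append(
                {
                    "component": t.component_name,
                    "frequency_cm1": _FLOAT_FMT % m.frequency,
                    "intensity": _FLOAT_FMT % m.intensity,
                    "label": m.label,
                    "fwhm": "" if t.default_fwhm is None else _FLOAT_FMT % t.default_fwhm,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_basis(basis: BasisMatrix, path) -> None:
    """Write a basis matrix as CSV: wavenumber_cm1 column + one per component."""
    df = pd.DataFrame(basis.matrix, columns=basis.column_names)
    df.insert(0, "wavenumber_cm1", basis.grid.points)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_basis(path) -> BasisMatrix:
    df = pd.read_csv(path, comment="#")
    if "wavenumber_cm1" not in df.columns or df.shape[1] < 2:
        raise FormatError(
            f"{Path(path).name}: need a wavenumber_cm1 column plus components"
        )
    names = [c for c in df.columns if c != "wavenumber_cm1"]
    return BasisMatrix(
        WavenumberGrid(df["wavenumber_cm1"].to_numpy(float)),
        df[names].to_numpy(float),
        names,
    )


# --------------------------------------------------------------------------
# Run configuration


_CONFIG_SCHEMA: dict[str, dict[str, type]] = {
    "grid": {"lo": float, "hi": float, "step": float},
    "fwhm": {},  # scalar
    "normalize": {"enabled": bool, "center": float, "halfwidth": float},
    "baseline": {"enabled": bool},
    "fix": None,  # free mapping component -> value
    "onset": {"frac": float},
    "plateau": {"rel_tol": float, "min_span": int},
    "noise": {"sigma": float, "decay_rate": float},
    "fit": {"scale_gauge": bool},
    "input": {"mode": str, "spectra_dir": str, "pattern": str, "peak_table": str},
    "output": {"dir": str},
    "seed": {},  # scalar
}

_DEFAULTS = {
    "grid": {"lo": 1150.0, "hi": 1800.0, "step": 1.0},
    "fwhm": 10.0,
    "normalize": {"enabled": True, "center": 1390.0, "halfwidth": 15.0},
    "baseline": {"enabled": False},
    "fix": {"Form": 1.0},
    "onset": {"frac": 0.05},
    "plateau": {"rel_tol": 0.05, "min_span": 3},
    "noise": {"sigma": 0.005, "decay_rate": 0.1},
    "fit": {"scale_gauge": True},
    "input": {"mode": "simulate", "spectra_dir": "", "pattern": "t{hour}.csv", "peak_table": ""},
    "output": {"dir": "ramanlcf_out"},
    "seed": 1234,
}


class RunConfig(dict):
    """Validated, fully-resolved pipeline configuration.

    Behaves as a nested dict mirroring the YAML layout; unknown keys are
    rejected at load time so typos cannot silently fall back to defaults.
    """

    @classmethod
    def from_mapping(cls, data: dict | None) -> "RunConfig":
        data = data or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        resolved = {}
        unknown = set(data) - set(_CONFIG_SCHEMA)
        if unknown:
            raise ConfigError(
                f"unknown config key(s) {sorted(unknown)}; "
                f"allowed: {sorted(_CONFIG_SCHEMA)}"
            )
        for key, default in _DEFAULTS.items():
            if not isinstance(default, dict):
                resolved[key] = data.get(key, default)
                continue
            sub_schema = _CONFIG_SCHEMA[key]
            given = data.get(key, {})
            if not isinstance(given, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            if sub_schema is not None:
                bad = set(given) - set(sub_schema)
                if bad:
                    raise ConfigError(
                        f"unknown key(s) {sorted(bad)} under {key!r}; "
                        f"allowed: {sorted(sub_schema)}"
                    )
            merged = dict(default)
            merged.update(given)
            resolved[key] = merged
        cfg = cls(resolved)
        cfg._validate()
        return cfg

    def _validate(self):
        g = self["grid"]
        if not g["lo"] < g["hi"]:
            raise ConfigError("grid.lo must be < grid.hi")
        if not g["step"] > 0:
            raise ConfigError("grid.step must be > 0")
        if not self["fwhm"] > 0:
            raise ConfigError("fwhm must be > 0")
        if self["input"]["mode"] not in ("simulate", "load"):
            raise ConfigError("input.mode must be 'simulate' or 'load'")
        for comp, val in self["fix"].items():
            if not isinstance(val, (int, float)) or val < 0:
                raise ConfigError(f"fix[{comp!r}] must be a number >= 0")
        if not isinstance(self["seed"], int):
            raise ConfigError("seed must be an integer")

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dict(self), sort_keys=True), encoding="utf-8"
        )


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, applying defaults for absent keys."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is not None:
            data = loaded
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, dict) and isinstance(data.get(key), dict):
                data[key].update(val)
            else:
                data[key] = val
    return RunConfig.from_mapping(data)
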