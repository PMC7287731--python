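"""Pure-component Raman spectra from vibrational peak tables.

A quantum-chemistry code delivers, for each candidate reaction species, a
list of vibrational modes (frequency in cm^-1, relative Raman intensity).
This module turns such a peak list into a sampled spectrum by broadening
each mode with a Lorentzian line shape on a common wavenumber grid, the
standard way simulated vibrational spectra are compared with experiment.

Conventions
-----------
* Mode intensity is interpreted as the **band area** (integrated intensity),
  not the peak height.  The integral of a Lorentzian is independent of its
  width, so linear-combination coefficients obtained downstream do not
  change when the broadening FWHM is changed.
* The default broadening is a 10 cm^-1 FWHM Lorentzian; a peak table may
  carry a per-component override (used here for the sharp atmospheric O2
  line, broadened at 4 cm^-1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, InvalidParameterError

__all__ = [
    "VibrationalMode",
    "ComponentPeakTable",
    "WavenumberGrid",
    "Spectrum",
    "lorentzian",
    "build_spectrum",
    "component_library",
    "DEFAULT_FWHM",
]

#: Default Lorentzian full width at half maximum, cm^-1.
DEFAULT_FWHM = 10.0


@dataclass(frozen=True)
class VibrationalMode:
    """One Raman-active vibrational mode.

    Parameters
    ----------
    frequency
        Vibrational frequency (Raman shift) in cm^-1; must be positive.
    intensity
        Relative Raman intensity in arbitrary units, interpreted as the
        integrated band area; must be >= 0.
    label
        Optional free-text assignment, e.g. ``"delta(HOH)"``.
    """

    frequency: float
    intensity: float
    label: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.frequency) and self.frequency > 0):
            raise InvalidParameterError(
                f"mode frequency must be finite and > 0, got {self.frequency!r}"
            )
        if not (math.isfinite(self.intensity) and self.intensity >= 0):
            raise InvalidParameterError(
                f"mode intensity must be finite and >= 0, got {self.intensity!r}"
            )


@dataclass(frozen=True)
class ComponentPeakTable:
    """The Raman-active modes of one chemical component.

    ``default_fwhm`` optionally overrides the broadening width for this
    component only (e.g. a sharp gas-phase line among solution bands).
    """

    component_name: str
    modes: tuple[VibrationalMode, ...]
    default_fwhm: float | None = None

    def __init__(self, component_name, modes, default_fwhm=None):
        object.__setattr__(self, "component_name", str(component_name))
        object.__setattr__(self, "modes", tuple(modes))
        object.__setattr__(self, "default_fwhm", default_fwhm)
        self.__post_init__()

    def __post_init__(self):
        if not self.component_name:
            raise InvalidParameterError("component_name must be non-empty")
        freqs = [m.frequency for m in self.modes]
        if len(set(freqs)) != len(freqs):
            raise InvalidParameterError(
                f"component {self.component_name!r}: duplicate mode frequencies"
            )
        if self.default_fwhm is not None and not self.default_fwhm > 0:
            raise InvalidParameterError(
                f"component {self.component_name!r}: default_fwhm must be > 0"
            )

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([m.frequency for m in self.modes], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([m.intensity for m in self.modes], dtype=float)

    def scaled(self, factor: float) -> "ComponentPeakTable":
        """Return a copy with every mode intensity multiplied by ``factor``."""
        return ComponentPeakTable(
            self.component_name,
            tuple(
                VibrationalMode(m.frequency, m.intensity * factor, m.label)
                for m in self.modes
            ),
            self.default_fwhm,
        )


class WavenumberGrid:
    """Strictly increasing sequence of wavenumbers (cm^-1)."""

    __slots__ = ("points",)

    def __init__(self, points):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise GridError("grid needs at least 2 points in one dimension")
        if not np.all(np.isfinite(pts)):
            raise GridError("grid points must all be finite")
        if not np.all(np.diff(pts) > 0):
            raise GridError("grid points must be strictly increasing")
        self.points = pts
        self.points.setflags(write=False)

    @classmethod
    def regular(cls, lo: float, hi: float, step: float = 1.0) -> "WavenumberGrid":
        """Regular grid from ``lo`` to ``hi`` inclusive with spacing ``step``."""
        if step <= 0:
            raise GridError("grid step must be > 0")
        n = int(round((hi - lo) / step))
        if n < 1:
            raise GridError(f"grid [{lo}, {hi}] with step {step} has < 2 points")
        return cls(lo + step * np.arange(n + 1))

    @classmethod
    def default(cls) -> "WavenumberGrid":
        """The analysis region used throughout: 1150-1800 cm^-1, 1 cm^-1 step."""
        return cls.regular(1150.0, 1800.0, 1.0)

    def __len__(self):
        return self.points.size

    def __eq__(self, other):
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.points, other.points
        )

    def __hash__(self):
        return hash((self.points.size, self.points[0], self.points[-1]))

    def __repr__(self):
        return (
            f"WavenumberGrid({self.points[0]:g}..{self.points[-1]:g} cm^-1, "
            f"{self.points.size} pts)"
        )

    @property
    def lo(self) -> float:
        return float(self.points[0])

    @property
    def hi(self) -> float:
        return float(self.points[-1])


class Spectrum:
    """Sampled intensity versus wavenumber on a :class:`WavenumberGrid`."""

    __slots__ = ("grid", "values")

    def __init__(self, grid: WavenumberGrid, values):
        vals = np.asarray(values, dtype=float)
        if vals.shape != grid.points.shape:
            raise GridError(
                f"values length {vals.size} does not match grid length {len(grid)}"
            )
        if not np.all(np.isfinite(vals)):
            raise GridError("spectrum values must all be finite")
        self.grid = grid
        self.values = vals
        self.values.setflags(write=False)

    def __len__(self):
        return len(self.grid)

    def __eq__(self, other):
        return (
            isinstance(other, Spectrum)
            and self.grid == other.grid
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self):
        return f"Spectrum({self.grid!r}, max={self.values.max():.4g})"

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, self.values * factor)

    def with_values(self, values) -> "Spectrum":
        return Spectrum(self.grid, values)


def lorentzian(x, center: float, fwhm: float, area: float = 1.0):
    """Area-normalized Lorentzian line shape.

    L(x) = (area / pi) * gamma / ((x - center)^2 + gamma^2),  gamma = fwhm / 2

    so that the integral over the real line is ``area`` and the peak height
    is ``2 * area / (pi * fwhm)``.  ``x`` may be a scalar or array.
    """
    if not fwhm > 0:
        raise InvalidParameterError(f"fwhm must be > 0, got {fwhm!r}")
    gamma = fwhm / 2.0
    x = np.asarray(x, dtype=float)
    out = (area / math.pi) * gamma / ((x - center) ** 2 + gamma**2)
    return float(out) if out.ndim == 0 else out


def build_spectrum(
    peaks: ComponentPeakTable,
    grid: WavenumberGrid,
    fwhm: float = DEFAULT_FWHM,
) -> Spectrum:
    """Broaden a peak table into a sampled spectrum.

    Each mode contributes one Lorentzian with area equal to its relative
    intensity; the spectrum is the pointwise sum.  The component's
    ``default_fwhm``, when set, takes precedence over ``fwhm``.

    An empty peak table yields an all-zero spectrum with a warning.
    """
    if not fwhm > 0:
        raise InvalidParameterError(f"fwhm must be > 0, got {fwhm!r}")
    eff_fwhm = peaks.default_fwhm if peaks.default_fwhm is not None else fwhm
    values = np.zeros(len(grid))
    if not peaks.modes:
        warnings.warn(
            f"component {peaks.component_name!r} has no modes; spectrum is zero",
            stacklevel=2,
        )
        return Spectrum(grid, values)
    for mode in peaks.modes:
        values += lorentzian(grid.points, mode.frequency, eff_fwhm, mode.intensity)
    return Spectrum(grid, values)


def component_library() -> list[ComponentPeakTable]:
    """Six-component reference library for formamide-on-silica monitoring.

    Peak positions follow the published band assignments for the
    formamide / HCN-chemistry system in the 1150-1800 cm^-1 window:

    * ``Form`` (formamide): symmetric and antisymmetric amide stretches at
      1300 and 1670 cm^-1, in-plane NH2 bend at 1600 cm^-1, in-plane CH
      bend at 1390 cm^-1 (the normalization reference band).
    * ``H2O``: the delta(HOH) bend at 1640 cm^-1.
    * ``DAMN`` (diaminomaleonitrile): fingerprints at 1325 and 1610 cm^-1.
    * ``Purine``: strongest band at 1485 cm^-1, weaker bands at 1270
      (shoulder) and 1230 cm^-1.
    * ``AI`` (5-aminoimidazole): no published positions for this window
      exist beyond a high-frequency shoulder of the 1390 cm^-1 formamide
      band; the table is a synthetic stand-in placing that shoulder at
      1410 cm^-1 plus bands overlapping DAMN (1325) and purine (1485).
    * ``O2``: the sharp atmospheric nu(O=O) line at 1555 cm^-1, broadened
      at 4 cm^-1 instead of the solution-phase default.

    Relative intensities are generator choices (they are not published);
    within each component the assigned strongest band is strongest.  The
    formamide 1390/1300 area ratio is set to 0.54, the band ratio observed
    at the start of reaction when the mixture is essentially pure formamide.
    """
    return [
        ComponentPeakTable(
            "Form",
            (
                VibrationalMode(1300.0, 1.0, "nu_s(amide)"),
                VibrationalMode(1390.0, 0.54, "delta(CH)"),
                VibrationalMode(1600.0, 0.35, "delta(NH2)"),
                VibrationalMode(1670.0, 0.65, "nu_as(amide)"),
            ),
        ),
        ComponentPeakTable(
            "H2O",
            (VibrationalMode(1640.0, 1.0, "delta(HOH)"),),
        ),
        ComponentPeakTable(
            "DAMN",
            (
                VibrationalMode(1325.0, 1.0, "fingerprint"),
                VibrationalMode(1610.0, 0.8, "fingerprint"),
            ),
        ),
        ComponentPeakTable(
            "AI",
            (
                VibrationalMode(1410.0, 1.0, "synthetic: 1390 shoulder"),
                VibrationalMode(1325.0, 0.5, "synthetic: DAMN overlap"),
                VibrationalMode(1485.0, 0.4, "synthetic: purine overlap"),
            ),
        ),
        ComponentPeakTable(
            "Purine",
            (
                VibrationalMode(1485.0, 1.0, "ring stretch"),
                VibrationalMode(1270.0, 0.45, "shoulder"),
                VibrationalMode(1230.0, 0.3, "weak"),
            ),
        ),
        ComponentPeakTable(
            "O2",
            (VibrationalMode(1555.0, 1.0, "nu(O=O), atmospheric"),),
            default_fwhm=4.0,
        ),
    ]
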