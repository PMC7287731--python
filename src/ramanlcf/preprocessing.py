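"""Common-grid resampling, windowing and reference-band normalization.

The monitoring protocol normalizes every spectrum to the intense formamide
CH-bend feature at 1390 cm^-1, on the assumption that the formamide
concentration stays constant (large excess, low conversion).  Dividing by
that reference removes global intensity fluctuations — instrumental drift
and the progressive self-absorption decay — because those act as a single
multiplicative scale on the whole spectrum.

The reference is located as the *maximum* inside a window around the
nominal band center rather than the value at exactly 1390 cm^-1, which
makes it robust to small wavenumber-calibration shifts; the default
half-width of 15 cm^-1 keeps the neighbouring DAMN band at 1325 cm^-1 out
of the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyWindowError, GridError, NormalizationError
from .spectral_model import Spectrum, WavenumberGrid

__all__ = [
    "NormalizationConfig",
    "resample",
    "clip_window",
    "normalize_to_band",
    "subtract_linear_baseline",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Where to look for the reference band.

    reference_center : cm^-1, nominal band position (default 1390).
    window_halfwidth : cm^-1, half-width of the search window (default 15).
    """

    reference_center: float = 1390.0
    window_halfwidth: float = 15.0

    def __post_init__(self):
        if not self.window_halfwidth > 0:
            raise NormalizationError("window_halfwidth must be > 0")


def resample(spectrum: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    The target grid must lie inside the source range: no extrapolation is
    performed.  Values at coincident grid points are reproduced exactly.
    """
    src = spectrum.grid.points
    if target.lo < src[0] or target.hi > src[-1]:
        raise GridError(
            f"target grid [{target.lo:g}, {target.hi:g}] extends beyond "
            f"source range [{src[0]:g}, {src[-1]:g}]; no extrapolation"
        )
    return Spectrum(target, np.interp(target.points, src, spectrum.values))


def clip_window(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Restrict a spectrum to wavenumbers ``lo <= w <= hi``."""
    if not lo < hi:
        raise EmptyWindowError(f"need lo < hi, got [{lo!r}, {hi!r}]")
    mask = (spectrum.grid.points >= lo) & (spectrum.grid.points <= hi)
    if mask.sum() < 2:
        raise EmptyWindowError(
            f"window [{lo:g}, {hi:g}] selects {int(mask.sum())} grid point(s)"
        )
    return Spectrum(
        WavenumberGrid(spectrum.grid.points[mask]), spectrum.values[mask]
    )


def _window_max(spectrum: Spectrum, center: float, halfwidth: float) -> float:
    mask = np.abs(spectrum.grid.points - center) <= halfwidth
    if not mask.any():
        raise EmptyWindowError(
            f"window {center:g} +/- {halfwidth:g} cm^-1 misses the grid "
            f"[{spectrum.grid.lo:g}, {spectrum.grid.hi:g}]"
        )
    return float(spectrum.values[mask].max())


def normalize_to_band(
    spectrum: Spectrum, config: NormalizationConfig | None = None
) -> Spectrum:
    """Divide a spectrum by the maximum inside the reference-band window.

    After the call the window maximum equals 1 exactly.  The operation is
    idempotent and scale-invariant, and leaves every band-intensity ratio
    unchanged (it is a single global division).
    """
    config = config or NormalizationConfig()
    ref = _window_max(spectrum, config.reference_center, config.window_halfwidth)
    if not ref > 0:
        raise NormalizationError(
            f"reference band absent: window maximum {ref:g} <= 0 at "
            f"{config.reference_center:g} +/- {config.window_halfwidth:g} cm^-1"
        )
    return spectrum.scaled(1.0 / ref)


def subtract_linear_baseline(spectrum: Spectrum, quantile: float = 0.1) -> Spectrum:
    """Remove a linear offset fitted to the lowest-intensity points.

    A straight line is least-squares fitted through the points whose
    intensity falls below the given quantile (signal-free regions for a
    sparse band pattern) and subtracted.  Off by default in the pipeline:
    the monitoring protocol applies no baseline correction.
    """
    w, v = spectrum.grid.points, spectrum.values
    cut = np.quantile(v, quantile)
    mask = v <= cut
    if mask.sum() < 2:
        mask = np.argsort(v)[:2]
    coeffs = np.polyfit(w[mask], v[mask], 1)
    return spectrum.with_values(v - np.polyval(coeffs, w))
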