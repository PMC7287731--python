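"""Coefficient trajectories from a monitored reaction series.

Every spectrum in a time series is fitted independently against the same
basis (no temporal smoothing or regularization — trend statements are made
after the fact), producing one coefficient-versus-time curve per free
component.  Simple threshold detectors then extract the kinetic landmarks
of interest: the onset time at which a product becomes detectable and the
plateau time after which a coefficient stays essentially constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConvergenceError,
    EmptyWindowError,
    InvalidParameterError,
    RatioError,
)
from .lcf import BasisMatrix, LCFResult, fit_spectrum
from .preprocessing import _window_max
from .spectral_model import Spectrum

__all__ = [
    "ReactionSeries",
    "CoefficientTrajectory",
    "SeriesFit",
    "fit_series",
    "detect_onset",
    "detect_plateau",
    "band_ratio",
]


@dataclass(frozen=True)
class ReactionSeries:
    """Time-stamped spectra of one monitored reaction.

    times are hours since the start of reaction, strictly increasing; the
    reference experiment collects one spectrum per hour for 12 h.
    """

    times: np.ndarray
    spectra: tuple[Spectrum, ...]

    def __init__(self, times, spectra):
        t = np.asarray(times, dtype=float)
        sp = tuple(spectra)
        if t.ndim != 1 or t.size != len(sp):
            raise InvalidParameterError(
                f"{t.size} times but {len(sp)} spectra"
            )
        if t.size and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "spectra", sp)

    def __len__(self):
        return self.times.size

    def map(self, fn) -> "ReactionSeries":
        """Apply a Spectrum -> Spectrum transform to every time point."""
        return ReactionSeries(self.times, [fn(s) for s in self.spectra])


@dataclass(frozen=True)
class CoefficientTrajectory:
    """One component's LCF weight as a function of time."""

    component: str
    times: np.ndarray
    coefficients: np.ndarray

    def __init__(self, component, times, coefficients):
        t = np.asarray(times, dtype=float)
        c = np.asarray(coefficients, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidParameterError("times/coefficients shape mismatch")
        if np.any(c < 0):
            raise InvalidParameterError("coefficients must be >= 0")
        t.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "component", str(component))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "coefficients", c)

    def __len__(self):
        return self.times.size


@dataclass(frozen=True)
class SeriesFit:
    """Full outcome of fitting a reaction series.

    trajectories : one per basis component (fixed components included, their
        trajectory is constant at the fixed value).
    residual_norms : per-time-point fit residual ||P C - D||_2.
    converged : per-time-point flag; a failed fit is recorded as False with
        zero coefficients and NaN residual, and fitting continues.
    results : the underlying per-point LCFResult (None where failed).
    """

    times: np.ndarray
    trajectories: dict[str, CoefficientTrajectory]
    residual_norms: np.ndarray
    converged: np.ndarray
    results: tuple[LCFResult | None, ...]

    def trajectory(self, component: str) -> CoefficientTrajectory:
        return self.trajectories[component]


def fit_series(
    series: ReactionSeries,
    P: BasisMatrix,
    fixed: dict[str, float] | None = None,
    *,
    scale_gauge: bool = True,
) -> SeriesFit:
    """Fit every spectrum of the series independently against ``P``.

    Spectra must already be resampled (and normalized, if desired) onto the
    basis grid.  ``scale_gauge`` defaults to True: reaction series carry an
    arbitrary, time-varying global intensity scale, and the gauge fit pins
    the fixed component exactly while cancelling that scale (see
    :mod:`ramanlcf.lcf`).  A convergence failure at one time point is
    flagged and does not abort the remaining fits.
    """
    n_t = len(series)
    names = list(P.column_names)
    coeffs = np.zeros((n_t, len(names)))
    residuals = np.full(n_t, np.nan)
    converged = np.zeros(n_t, dtype=bool)
    results: list[LCFResult | None] = []
    for i, spec in enumerate(series.spectra):
        try:
            res = fit_spectrum(spec, P, fixed, scale_gauge=scale_gauge)
        except ConvergenceError:
            results.append(None)
            continue
        coeffs[i] = res.coefficients.values
        residuals[i] = res.residual_norm
        converged[i] = True
        results.append(res)
    trajectories = {
        name: CoefficientTrajectory(name, series.times, coeffs[:, j])
        for j, name in enumerate(names)
    }
    return SeriesFit(
        times=series.times,
        trajectories=trajectories,
        residual_norms=residuals,
        converged=converged,
        results=tuple(results),
    )


def detect_onset(traj: CoefficientTrajectory, frac: float = 0.05) -> float | None:
    """Earliest time at which the coefficient reaches ``frac`` of its maximum.

    Returns None for an identically-zero trajectory.  Monotone in ``frac``:
    a larger threshold can only delay the detected onset.
    """
    if not 0 < frac < 1:
        raise InvalidParameterError(f"frac must be in (0, 1), got {frac!r}")
    peak = traj.coefficients.max() if len(traj) else 0.0
    if peak <= 0:
        return None
    hits = np.flatnonzero(traj.coefficients >= frac * peak)
    return float(traj.times[hits[0]]) if hits.size else None


def detect_plateau(
    traj: CoefficientTrajectory,
    rel_tol: float = 0.05,
    min_span: int = 3,
) -> float | None:
    """Earliest time from which the trajectory stays flat to the end.

    A plateau starts at the first time point such that every later value
    (the tail must span at least ``min_span`` points) lies within
    ``rel_tol`` (relative) of the tail mean.  Returns None when no such
    tail exists — e.g. for a strictly growing trajectory.
    """
    if min_span < 2:
        raise InvalidParameterError(f"min_span must be >= 2, got {min_span!r}")
    c = traj.coefficients
    n = c.size
    for i in range(0, n - min_span + 1):
        tail = c[i:]
        mu = tail.mean()
        if np.all(np.abs(tail - mu) <= rel_tol * abs(mu)):
            return float(traj.times[i])
    return None


def band_ratio(
    spectrum: Spectrum,
    num_center: float,
    den_center: float,
    halfwidth: float = 15.0,
) -> float:
    """Ratio of window-maximum intensities at two band positions.

    Both windows are ``center +/- halfwidth``.  The ratio is invariant
    under global rescaling of the spectrum, which makes it comparable
    across raw and normalized spectra of the same shape; note, however,
    that trends quoted for spectra normalized at one of the two bands pin
    that band's window to 1 and can invert the apparent direction relative
    to raw data.
    """
    num = _window_max(spectrum, num_center, halfwidth)
    den = _window_max(spectrum, den_center, halfwidth)
    if not den > 0:
        raise RatioError(
            f"denominator window {den_center:g} +/- {halfwidth:g} cm^-1 "
            f"has non-positive maximum {den:g}"
        )
    return num / den
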