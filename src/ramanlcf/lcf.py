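"""Constrained linear-combination fitting (LCF) of spectra.

A measured spectrum D (m grid points) is modelled as a non-negative linear
combination of n pure-component reference spectra collected as the columns
of a basis matrix P:

    min_C  || P C - D ||_2^2      subject to  C >= 0,

optionally with designated components held at fixed values — here the
formamide coefficient is fixed to 1, expressing that the reactant is in
large excess and its concentration is effectively constant.  The weights C
track the relative spectral amounts of the species.

The non-negative least-squares subproblem is solved by a Lawson-Hanson
active-set iteration implemented in this module (the fit is the central
computation of the package, so it is first-party and certified by KKT
diagnostics rather than delegated).  Fixed components are handled in two
ways:

``scale_gauge=False`` (default)
    Residual subtraction: the fixed contribution is subtracted from D and
    the free components are fitted to the remainder.  The constraint is
    met exactly, and the fixed values are taken at face value on the
    intensity scale of D.

``scale_gauge=True``
    Gauge fixing, for data known only up to a global intensity scale
    (self-absorption decay, window-max normalization).  The full problem
    is solved with every component free; the scale s is read off as the
    ratio of the fixed component's fitted weight to its prescribed value,
    and all coefficients are divided by s.  The fixed component then holds
    its value exactly and a global scale on D provably cancels.  Requires
    a single fixed component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, GridError, InvalidParameterError
from .spectral_model import (
    ComponentPeakTable,
    Spectrum,
    WavenumberGrid,
    build_spectrum,
    DEFAULT_FWHM,
)

__all__ = [
    "BasisMatrix",
    "CoefficientVector",
    "LCFResult",
    "solve_nnls",
    "nnls_with_diagnostics",
    "fit_spectrum",
    "build_basis",
]


class BasisMatrix:
    """Pure-component spectra as columns on a shared wavenumber grid."""

    __slots__ = ("grid", "matrix", "column_names")

    def __init__(self, grid: WavenumberGrid, matrix, column_names):
        mat = np.asarray(matrix, dtype=float)
        names = list(column_names)
        if mat.ndim != 2:
            raise GridError("basis matrix must be 2-D (grid points x components)")
        m, n = mat.shape
        if m != len(grid):
            raise GridError(
                f"basis has {m} rows but the grid has {len(grid)} points"
            )
        if n != len(names):
            raise GridError(f"{n} columns but {len(names)} column names")
        if len(set(names)) != len(names):
            raise InvalidParameterError(f"duplicate component names: {names}")
        if m <= n:
            raise InvalidParameterError(
                f"need more grid points than components (m={m}, n={n})"
            )
        zero = ~np.any(mat != 0.0, axis=0)
        if zero.any():
            bad = [names[i] for i in np.flatnonzero(zero)]
            raise InvalidParameterError(f"all-zero basis column(s): {bad}")
        self.grid = grid
        self.matrix = mat
        self.column_names = names

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> Spectrum:
        return Spectrum(self.grid, self.matrix[:, self.index(name)])

    def index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise InvalidParameterError(
                f"unknown component {name!r}; basis has {self.column_names}"
            ) from None

    def __repr__(self):
        return f"BasisMatrix({self.column_names}, m={self.matrix.shape[0]})"


def build_basis(
    library: list[ComponentPeakTable],
    grid: WavenumberGrid | None = None,
    fwhm: float = DEFAULT_FWHM,
) -> BasisMatrix:
    """Broaden a component library into a basis matrix on ``grid``."""
    grid = grid or WavenumberGrid.default()
    cols = [build_spectrum(t, grid, fwhm).values for t in library]
    names = [t.component_name for t in library]
    return BasisMatrix(grid, np.column_stack(cols), names)


@dataclass(frozen=True)
class CoefficientVector:
    """Named non-negative LCF weights, with the fixed components recorded."""

    names: tuple[str, ...]
    values: np.ndarray
    fixed_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != self.values.size:
            raise InvalidParameterError("names/values length mismatch")
        if np.any(self.values < 0):
            raise InvalidParameterError("coefficients must be >= 0")
        for name, val in self.fixed_map.items():
            got = self.values[self.names.index(name)]
            if got != val:
                raise InvalidParameterError(
                    f"fixed component {name!r} holds {got!r}, expected {val!r}"
                )

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


@dataclass(frozen=True)
class LCFResult:
    """Outcome of one constrained fit.

    residual_norm is ||P C - D||_2 on the full model (after any gauge
    rescaling of D); kkt_max_violation certifies optimality of the NNLS
    subproblem (~0 gradient on active components, gradient >= 0 on the
    zeroed ones), relative to the problem scale.  ``scale`` is the global
    intensity factor divided out in gauge mode (1.0 otherwise).
    """

    coefficients: CoefficientVector
    residual_norm: float
    fitted: Spectrum
    kkt_max_violation: float
    scale: float = 1.0


def _kkt_violation(A: np.ndarray, b: np.ndarray, x: np.ndarray) -> float:
    """Max KKT violation of x for min ||Ax-b||, x>=0, relative to scale."""
    g = A.T @ (A @ x - b)
    scale = max(np.abs(A.T @ b).max(), 1.0)
    active = x > 0
    viol = 0.0
    if active.any():
        viol = np.abs(g[active]).max()
    if (~active).any():
        viol = max(viol, max(0.0, -(g[~active]).min()))
    return float(viol / scale)


def solve_nnls(
    A,
    b,
    *,
    tol: float | None = None,
    max_iter: int | None = None,
) -> np.ndarray:
    """Non-negative least squares by Lawson-Hanson active-set iteration.

    Returns x >= 0 minimizing ||A x - b||_2^2.  At the solution the KKT
    conditions hold: the gradient g = A^T(Ax - b) vanishes (to tolerance)
    on components with x_i > 0 and is >= -tol on components with x_i = 0.

    Parameters
    ----------
    A : (m, k) array, m >= k, no all-zero column.
    b : (m,) array.
    tol : dual-feasibility/termination tolerance; default
        ``1e-10 * max(1, ||A^T b||_inf)``.
    max_iter : cap on active-set changes, default ``10 * k``; exceeding it
        raises :class:`ConvergenceError` carrying the cap and the residual.

    Notes
    -----
    The entering component is the one with the most negative gradient
    (largest dual w = -g), first index on exact ties.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2:
        raise InvalidParameterError("A must be 2-D")
    m, k = A.shape
    if b.size != m:
        raise InvalidParameterError(f"b has {b.size} entries, A has {m} rows")
    if m < k:
        raise InvalidParameterError(f"underdetermined system (m={m} < k={k})")
    if not np.any(A != 0.0, axis=0).all():
        raise InvalidParameterError("A has an all-zero column")

    if tol is None:
        tol = 1e-10 * max(np.abs(A.T @ b).max(), 1.0)
    if max_iter is None:
        max_iter = 10 * k

    x = np.zeros(k)
    passive = np.zeros(k, dtype=bool)
    outer = 0
    while True:
        w = A.T @ (b - A @ x)  # dual; w_i = -gradient_i
        w_masked = np.where(passive, -np.inf, w)
        j = int(np.argmax(w_masked))  # first index on exact ties
        if w_masked[j] <= tol:
            break  # KKT satisfied on the zero set
        outer += 1
        if outer > max_iter:
            raise ConvergenceError(
                f"NNLS active-set iteration cap ({max_iter}) exceeded",
                iterations=outer,
                residual_norm=float(np.linalg.norm(A @ x - b)),
            )
        passive[j] = True
        while True:
            idx = np.flatnonzero(passive)
            s_p, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            if np.all(s_p > 0):
                x[:] = 0.0
                x[idx] = s_p
                break
            # Partial step toward s_p; the blocking component hits zero and
            # leaves the passive set, guaranteeing inner-loop progress.
            xp = x[idx]
            neg = np.flatnonzero(s_p <= 0)
            denom = xp[neg] - s_p[neg]
            ratios = np.where(denom > 0, xp[neg] / np.where(denom > 0, denom, 1.0), 0.0)
            alpha = float(ratios.min())
            x[idx] = xp + alpha * (s_p - xp)
            x[idx[neg[int(np.argmin(ratios))]]] = 0.0
            zeroed = idx[x[idx] <= tol]
            x[zeroed] = 0.0
            passive[zeroed] = False
            if not passive.any():
                x[:] = 0.0
                break
    return x


def nnls_with_diagnostics(A, b, **kw) -> tuple[np.ndarray, float, float]:
    """solve_nnls plus (residual_norm, relative KKT violation)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    x = solve_nnls(A, b, **kw)
    return x, float(np.linalg.norm(A @ x - b)), _kkt_violation(A, b, x)


def fit_spectrum(
    D: Spectrum,
    P: BasisMatrix,
    fixed: dict[str, float] | None = None,
    *,
    scale_gauge: bool = False,
) -> LCFResult:
    """Fit one spectrum against the basis with non-negativity and fixed
    components.

    ``D`` must already be on the basis grid (resample upstream).  ``fixed``
    maps component names to prescribed non-negative coefficients; see the
    module docstring for the ``scale_gauge`` semantics.
    """
    if D.grid != P.grid:
        raise GridError("spectrum grid differs from basis grid; resample first")
    fixed = dict(fixed or {})
    for name, val in fixed.items():
        P.index(name)  # raises on unknown name
        if val < 0:
            raise InvalidParameterError(f"fixed value for {name!r} must be >= 0")

    names = tuple(P.column_names)
    A = P.matrix
    b = D.values

    if scale_gauge and fixed:
        if len(fixed) != 1:
            raise InvalidParameterError(
                "scale_gauge requires exactly one fixed component"
            )
        (fname, fval), = fixed.items()
        if fval <= 0:
            raise InvalidParameterError(
                "scale_gauge needs a positive fixed value to set the scale"
            )
        x_free, _, _ = nnls_with_diagnostics(A, b)
        fitted_fixed = x_free[P.index(fname)]
        if fitted_fixed <= 0:
            raise ConvergenceError(
                f"gauge component {fname!r} fitted at zero; "
                "cannot determine the global scale",
                iterations=0,
                residual_norm=float(np.linalg.norm(A @ x_free - b)),
            )
        scale = fitted_fixed / fval
        x = x_free / scale
        x[P.index(fname)] = fval  # exact by construction, kill rounding
        b_eff = b / scale
        kkt = _kkt_violation(A, b_eff, x)
    else:
        scale = 1.0
        b_eff = b
        free_idx = [i for i, n in enumerate(names) if n not in fixed]
        x = np.zeros(len(names))
        for name, val in fixed.items():
            x[P.index(name)] = val
        residual_target = b - A @ x
        if free_idx:
            x_sub, _, kkt = nnls_with_diagnostics(A[:, free_idx], residual_target)
            x[free_idx] = x_sub
        else:
            kkt = 0.0

    fitted_vals = A @ x
    return LCFResult(
        coefficients=CoefficientVector(names, x, fixed_map=fixed),
        residual_norm=float(np.linalg.norm(fitted_vals - b_eff)),
        fitted=Spectrum(P.grid, fitted_vals),
        kkt_max_violation=kkt,
        scale=float(scale),
    )
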