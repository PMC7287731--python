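"""Independent oracles for the constrained least-squares solver.

Both oracles avoid the Lawson-Hanson active-set path used by the package:
one enumerates every possible active set and solves the unconstrained
subproblem directly (exact global optimum for small k), the other runs
plain projected-gradient descent to high iteration count.
"""

from itertools import combinations

import numpy as np


def nnls_enumerate(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact NNLS by exhaustive active-set enumeration (small k only).

    The NNLS optimum zeroes some subset of coordinates and solves the
    unconstrained least squares on the rest; trying all 2^k subsets and
    keeping the best feasible candidate yields the global optimum.
    """
    m, k = A.shape
    best_x = np.zeros(k)
    best_obj = float(np.dot(b, b))
    for size in range(1, k + 1):
        for free in combinations(range(k), size):
            idx = list(free)
            s, *_ = np.linalg.lstsq(A[:, idx], b, rcond=None)
            if np.any(s < -1e-12):
                continue
            x = np.zeros(k)
            x[idx] = np.clip(s, 0.0, None)
            obj = float(np.sum((A @ x - b) ** 2))
            if obj < best_obj - 1e-14 * max(1.0, best_obj):
                best_obj, best_x = obj, x
    return best_x


def nnls_projected_gradient(
    A: np.ndarray, b: np.ndarray, n_iter: int = 200_000
) -> np.ndarray:
    """NNLS by projected gradient descent with fixed step 1/L."""
    AtA = A.T @ A
    Atb = A.T @ b
    L = float(np.linalg.eigvalsh(AtA).max())
    x = np.zeros(A.shape[1])
    step = 1.0 / L
    for _ in range(n_iter):
        x_new = np.clip(x - step * (AtA @ x - Atb), 0.0, None)
        if np.abs(x_new - x).max() < 1e-14:
            x = x_new
            break
        x = x_new
    return x
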