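"""Constrained linear-combination fit and the in-house NNLS solver."""

import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from ramanlcf import (
    BasisMatrix,
    ConvergenceError,
    GridError,
    InvalidParameterError,
    Spectrum,
    WavenumberGrid,
    build_basis,
    fit_spectrum,
    nnls_with_diagnostics,
    solve_nnls,
)

from _oracles import nnls_enumerate, nnls_projected_gradient


def _random_instance(rng, m=20, k=4):
    A = rng.normal(size=(m, k))
    b = rng.normal(size=m)
    return A, b


class TestSolveNNLS:
    def test_identity_clamps_negative_target(self):
        x = solve_nnls(np.eye(2), np.array([1.0, -1.0]))
        np.testing.assert_allclose(x, [1.0, 0.0], atol=1e-14)

    def test_exact_feasible_solution_recovered(self, rng):
        A = rng.normal(size=(30, 5))
        x0 = rng.uniform(0.5, 2.0, size=5)
        x = solve_nnls(A, A @ x0)
        np.testing.assert_allclose(x, x0, atol=1e-10)

    def test_matches_scipy_and_both_oracles(self, rng):
        for _ in range(30):
            A, b = _random_instance(rng)
            x, _, kkt = nnls_with_diagnostics(A, b)
            x_scipy, _ = scipy_nnls(A, b)
            x_enum = nnls_enumerate(A, b)
            x_pg = nnls_projected_gradient(A, b)
            np.testing.assert_allclose(x, x_scipy, atol=1e-9)
            np.testing.assert_allclose(x, x_enum, atol=1e-6)
            np.testing.assert_allclose(x, x_pg, atol=1e-6)
            assert kkt <= 1e-8

    def test_constrained_residual_never_beats_unconstrained(self, rng):
        for _ in range(20):
            A, b = _random_instance(rng)
            _, res, _ = nnls_with_diagnostics(A, b)
            res_free = np.linalg.norm(A @ np.linalg.lstsq(A, b, rcond=None)[0] - b)
            assert res >= res_free - 1e-12
            # equality when the unconstrained optimum is feasible
            x_free = np.linalg.lstsq(A, b, rcond=None)[0]
            if np.all(x_free >= 0):
                assert res == pytest.approx(res_free, abs=1e-10)

    def test_equality_when_unconstrained_feasible(self, rng):
        A = rng.normal(size=(25, 4))
        x0 = rng.uniform(1.0, 2.0, size=4)
        b = A @ x0 + 1e-3 * rng.normal(size=25)  # optimum stays interior
        _, res, _ = nnls_with_diagnostics(A, b)
        res_free = np.linalg.norm(A @ np.linalg.lstsq(A, b, rcond=None)[0] - b)
        assert res == pytest.approx(res_free, rel=1e-10)

    def test_permuting_columns_permutes_solution(self, rng):
        A, b = _random_instance(rng)
        perm = rng.permutation(A.shape[1])
        x = solve_nnls(A, b)
        x_perm = solve_nnls(A[:, perm], b)
        np.testing.assert_allclose(x_perm, x[perm], atol=1e-10)

    def test_input_validation(self, rng):
        with pytest.raises(InvalidParameterError):
            solve_nnls(np.zeros((5, 2)), np.ones(5))  # all-zero column
        with pytest.raises(InvalidParameterError):
            solve_nnls(rng.normal(size=(3, 5)), np.ones(3))  # m < k
        with pytest.raises(InvalidParameterError):
            solve_nnls(rng.normal(size=(5, 2)), np.ones(4))  # length mismatch

    def test_iteration_cap_raises_with_diagnostics(self, rng):
        A = rng.normal(size=(20, 6))
        x0 = rng.uniform(0.5, 1.5, size=6)
        b = A @ x0
        with pytest.raises(ConvergenceError) as exc:
            solve_nnls(A, b, max_iter=1)
        assert exc.value.iterations > 1
        assert exc.value.residual_norm >= 0


class TestBasisMatrix:
    def test_validation(self, grid, rng):
        m = len(grid)
        good = rng.random((m, 2)) + 0.1
        with pytest.raises(InvalidParameterError):
            BasisMatrix(grid, np.column_stack([good[:, 0], np.zeros(m)]), ["a", "b"])
        with pytest.raises(InvalidParameterError):
            BasisMatrix(grid, good, ["a", "a"])
        with pytest.raises(Exception):
            BasisMatrix(WavenumberGrid([1.0, 2.0]), np.ones((2, 2)) , ["a", "b"])

    def test_column_lookup(self, basis):
        col = basis.column("DAMN")
        assert col.values.max() > 0
        with pytest.raises(InvalidParameterError):
            basis.index("Adenine")


class TestFitSpectrum:
    def test_exact_two_component_recovery(self, basis):
        D = Spectrum(
            basis.grid,
            basis.column("Form").values + 0.3 * basis.column("DAMN").values,
        )
        res = fit_spectrum(D, basis, {"Form": 1.0})
        assert res.coefficients["DAMN"] == pytest.approx(0.3, abs=1e-8)
        for name in ("H2O", "AI", "Purine", "O2"):
            assert res.coefficients[name] == pytest.approx(0.0, abs=1e-8)
        assert res.residual_norm == pytest.approx(0.0, abs=1e-8)

    def test_pure_formamide_all_free_zero(self, basis):
        D = basis.column("Form")
        res = fit_spectrum(D, basis, {"Form": 1.0})
        assert np.all(res.coefficients.values[1:] == 0) or np.allclose(
            [res.coefficients[n] for n in basis.column_names if n != "Form"],
            0.0,
            atol=1e-10,
        )
        assert res.residual_norm == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_matches_enumeration_oracle(self, basis, rng):
        """Seeded noisy mixture: the fixed-formamide fit must agree with the
        exhaustive oracle applied to the same reduced problem."""
        D_clean = basis.column("Form").values + 0.2 * basis.column("Purine").values
        noise = rng.normal(0.0, 0.005 * D_clean.max(), size=D_clean.size)
        D = Spectrum(basis.grid, D_clean + noise)
        res = fit_spectrum(D, basis, {"Form": 1.0})
        free = [i for i, n in enumerate(basis.column_names) if n != "Form"]
        reduced_b = D.values - basis.column("Form").values
        x_oracle = nnls_enumerate(basis.matrix[:, free], reduced_b)
        got = np.array(
            [res.coefficients[basis.column_names[i]] for i in free]
        )
        np.testing.assert_allclose(got, x_oracle, atol=1e-6)
        assert res.kkt_max_violation <= 1e-8

    def test_grid_mismatch_raises(self, basis):
        other = WavenumberGrid.regular(1150, 1800, 2.0)
        D = Spectrum(other, np.ones(len(other)))
        with pytest.raises(GridError):
            fit_spectrum(D, basis)

    def test_unknown_fixed_component_raises(self, basis):
        D = basis.column("Form")
        with pytest.raises(InvalidParameterError):
            fit_spectrum(D, basis, {"Adenine": 1.0})

    def test_fixed_value_held_exactly(self, basis, rng):
        D = Spectrum(
            basis.grid,
            basis.column("Form").values
            + 0.5 * basis.column("H2O").values
            + rng.normal(0, 1e-3, len(basis.grid)),
        )
        for gauge in (False, True):
            res = fit_spectrum(D, basis, {"Form": 1.0}, scale_gauge=gauge)
            assert res.coefficients["Form"] == 1.0

    def test_gauge_mode_cancels_global_scale(self, basis):
        D = Spectrum(
            basis.grid,
            basis.column("Form").values + 0.25 * basis.column("DAMN").values,
        )
        res_a = fit_spectrum(D, basis, {"Form": 1.0}, scale_gauge=True)
        res_b = fit_spectrum(D.scaled(0.037), basis, {"Form": 1.0}, scale_gauge=True)
        np.testing.assert_allclose(
            res_a.coefficients.values, res_b.coefficients.values, atol=1e-10
        )
        assert res_b.scale == pytest.approx(0.037, rel=1e-8)

    def test_gauge_mode_needs_single_positive_fixed(self, basis):
        D = basis.column("Form")
        with pytest.raises(InvalidParameterError):
            fit_spectrum(D, basis, {"Form": 1.0, "H2O": 0.5}, scale_gauge=True)
        with pytest.raises(InvalidParameterError):
            fit_spectrum(D, basis, {"Form": 0.0}, scale_gauge=True)

    def test_gauge_mode_fails_when_reference_absent(self, basis):
        D = basis.column("DAMN")  # no formamide signal at all
        with pytest.raises(ConvergenceError):
            fit_spectrum(D, basis, {"Form": 1.0}, scale_gauge=True)

    def test_basis_column_permutation_invariance(self, library, grid):
        basis_a = build_basis(library, grid)
        basis_b = build_basis(library[::-1], grid)
        D = Spectrum(
            grid,
            basis_a.column("Form").values + 0.4 * basis_a.column("Purine").values,
        )
        res_a = fit_spectrum(D, basis_a, {"Form": 1.0})
        res_b = fit_spectrum(D, basis_b, {"Form": 1.0})
        for name in basis_a.column_names:
            assert res_a.coefficients[name] == pytest.approx(
                res_b.coefficients[name], abs=1e-9
            )
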