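"""Lorentzian band model and pure-component spectrum construction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ramanlcf import (
    ComponentPeakTable,
    InvalidParameterError,
    VibrationalMode,
    WavenumberGrid,
    build_spectrum,
    lorentzian,
)


class TestLorentzian:
    def test_peak_height_at_center(self):
        # unit area, FWHM 10 -> height 2/(10*pi)
        assert lorentzian(1390.0, 1390.0, 10.0, 1.0) == pytest.approx(
            2.0 / (10.0 * math.pi)
        )

    @pytest.mark.parametrize("fwhm", [4.0, 10.0, 25.0])
    def test_half_height_at_half_width(self, fwhm):
        center = 1500.0
        top = lorentzian(center, center, fwhm)
        assert lorentzian(center + fwhm / 2, center, fwhm) == pytest.approx(top / 2)
        assert lorentzian(center - fwhm / 2, center, fwhm) == pytest.approx(top / 2)

    def test_symmetric_about_center(self):
        offs = np.linspace(0.0, 80.0, 17)
        left = lorentzian(1400.0 - offs, 1400.0, 10.0, 2.0)
        right = lorentzian(1400.0 + offs, 1400.0, 10.0, 2.0)
        np.testing.assert_allclose(left, right, rtol=0, atol=0)

    def test_area_by_quadrature(self):
        # integral over +/-500 cm^-1 recovers the nominal area within 1%
        # (the residual tail of a gamma=5 Lorentzian beyond 500 is ~0.6%)
        area, _ = quad(lambda x: lorentzian(x, 0.0, 10.0, 3.0), -500.0, 500.0)
        assert area == pytest.approx(3.0, rel=0.01)

    @pytest.mark.parametrize("fwhm", [0.0, -3.0])
    def test_nonpositive_fwhm_rejected(self, fwhm):
        with pytest.raises(InvalidParameterError):
            lorentzian(1390.0, 1390.0, fwhm)


class TestDomainTypes:
    def test_mode_validation(self):
        with pytest.raises(InvalidParameterError):
            VibrationalMode(-5.0, 1.0)
        with pytest.raises(InvalidParameterError):
            VibrationalMode(1300.0, -0.1)
        with pytest.raises(InvalidParameterError):
            VibrationalMode(float("nan"), 1.0)

    def test_duplicate_mode_frequencies_rejected(self):
        with pytest.raises(InvalidParameterError):
            ComponentPeakTable(
                "X", (VibrationalMode(1300, 1.0), VibrationalMode(1300, 0.5))
            )

    def test_grid_must_increase(self):
        with pytest.raises(Exception):
            WavenumberGrid([1200.0, 1200.0, 1300.0])
        with pytest.raises(Exception):
            WavenumberGrid([1300.0])

    def test_regular_grid_endpoints(self):
        g = WavenumberGrid.regular(1150, 1800, 1.0)
        assert g.lo == 1150.0 and g.hi == 1800.0 and len(g) == 651


class TestBuildSpectrum:
    def test_empty_table_warns_and_is_zero(self, grid):
        table = ComponentPeakTable("empty", ())
        with pytest.warns(UserWarning):
            spec = build_spectrum(table, grid)
        assert not spec.values.any()

    def test_single_mode_peaks_at_nearest_grid_point(self, grid):
        table = ComponentPeakTable("F", (VibrationalMode(1390.3, 1.0),))
        spec = build_spectrum(table, grid)
        assert grid.points[np.argmax(spec.values)] == 1390.0

    def test_two_separated_modes_match_direct_sum(self, grid):
        table = ComponentPeakTable(
            "two", (VibrationalMode(1250.0, 1.0), VibrationalMode(1650.0, 1.0))
        )
        spec = build_spectrum(table, grid, fwhm=10.0)
        direct = lorentzian(grid.points, 1250.0, 10.0, 1.0) + lorentzian(
            grid.points, 1650.0, 10.0, 1.0
        )
        np.testing.assert_allclose(spec.values, direct, rtol=0, atol=0)
        # equal-intensity, well-separated bands have equal heights on-grid
        h1 = spec.values[grid.points == 1250.0][0]
        h2 = spec.values[grid.points == 1650.0][0]
        assert h1 == pytest.approx(h2, rel=1e-6)

    def test_linearity_in_intensities(self, grid, library):
        for table in library:
            base = build_spectrum(table, grid).values
            # power-of-two factor: bit-exact; generic factor: to rounding
            np.testing.assert_array_equal(
                build_spectrum(table.scaled(4.0), grid).values, 4.0 * base
            )
            np.testing.assert_allclose(
                build_spectrum(table.scaled(3.5), grid).values,
                3.5 * base,
                rtol=1e-12,
            )

    def test_shift_equivariance(self):
        table = ComponentPeakTable(
            "s", (VibrationalMode(1300.0, 1.0), VibrationalMode(1500.0, 0.4))
        )
        delta = 37.0
        shifted = ComponentPeakTable(
            "s",
            tuple(
                VibrationalMode(m.frequency + delta, m.intensity)
                for m in table.modes
            ),
        )
        g1 = WavenumberGrid.regular(1150, 1800, 1.0)
        g2 = WavenumberGrid.regular(1150 + delta, 1800 + delta, 1.0)
        np.testing.assert_array_equal(
            build_spectrum(table, g1).values, build_spectrum(shifted, g2).values
        )

    def test_per_component_fwhm_override(self):
        grid = WavenumberGrid.regular(1400, 1700, 0.5)
        sharp = ComponentPeakTable(
            "O2", (VibrationalMode(1555.0, 1.0),), default_fwhm=4.0
        )
        spec = build_spectrum(sharp, grid, fwhm=10.0)  # override wins
        assert spec.values.max() == pytest.approx(2.0 / (4.0 * math.pi), rel=1e-4)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        freqs=st.lists(
            st.floats(min_value=1200, max_value=1750),
            min_size=1,
            max_size=5,
            unique_by=lambda f: round(f, 1),
        ),
        intensities=st.lists(
            st.floats(min_value=0.01, max_value=5.0), min_size=5, max_size=5
        ),
    )
    def test_area_conservation(self, freqs, intensities):
        """Trapezoidal integral over +/-50 FWHM equals the summed mode areas
        within 1%."""
        modes = tuple(
            VibrationalMode(f, i) for f, i in zip(freqs, intensities)
        )
        table = ComponentPeakTable("rand", modes)
        lo = min(freqs) - 500.0
        hi = max(freqs) + 500.0
        grid = WavenumberGrid.regular(lo, hi, 0.25)
        spec = build_spectrum(table, grid, fwhm=10.0)
        total_area = sum(m.intensity for m in modes)
        integral = np.trapezoid(spec.values, grid.points)
        assert integral == pytest.approx(total_area, rel=0.01)


class TestComponentLibrary:
    def test_expected_components_and_fingerprints(self, library):
        by_name = {t.component_name: t for t in library}
        assert set(by_name) == {"Form", "H2O", "DAMN", "AI", "Purine", "O2"}
        assert sorted(by_name["DAMN"].frequencies) == [1325.0, 1610.0]
        assert list(by_name["H2O"].frequencies) == [1640.0]
        assert set(by_name["Form"].frequencies) == {1300.0, 1390.0, 1600.0, 1670.0}
        assert 1485.0 in by_name["Purine"].frequencies
        assert by_name["O2"].default_fwhm == 4.0

    def test_all_frequencies_inside_analysis_window(self, library):
        for table in library:
            assert np.all(table.frequencies >= 1150)
            assert np.all(table.frequencies <= 1800)

    def test_strongest_assigned_band_is_strongest(self, library):
        by_name = {t.component_name: t for t in library}
        purine = by_name["Purine"]
        assert purine.frequencies[np.argmax(purine.intensities)] == 1485.0
        form = by_name["Form"]
        assert form.frequencies[np.argmax(form.intensities)] == 1300.0
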