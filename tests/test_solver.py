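"""Equilibrium solver: pitch quartic, contact force, pressure inversion."""

import math

import numpy as np
import pytest

from helistent import (
    CMH2O_TO_PA,
    SolverError,
    ValidationError,
    WireMaterial,
    contact_line_force,
    diameter_under_pressure,
    equilibrium_pitch,
    fixture_generator,
    pressure_for_diameter,
    pressure_sweep,
)
from helistent.solver import _quartic_coeffs

from conftest import grid_pitch_oracle, paper_geometry, virtual_work_force_oracle


class TestEquilibriumPitch:
    def test_unloaded_diameter_returns_unloaded_pitch(
        self, paper_geometries, default_material
    ):
        for g in paper_geometries:
            assert equilibrium_pitch(g, default_material, g.d0) == pytest.approx(
                g.p0, rel=1e-9
            )

    def test_matches_grid_search_on_deployed_geometry(self, default_material):
        # d0 = 13.21 mm, p0 = 18.6 mm, 0.51 mm wire, compressed to 12.0 mm
        g = paper_geometry(0.51, 18.6)
        p_star = equilibrium_pitch(g, default_material, 12.0e-3)
        assert p_star > g.p0
        assert p_star == pytest.approx(
            grid_pitch_oracle(g, default_material, 12.0e-3), rel=1e-6
        )

    def test_pitch_increases_as_diameter_decreases(
        self, invivo_geometry, default_material
    ):
        ds = np.linspace(invivo_geometry.d0, 0.7 * invivo_geometry.d0, 30)
        ps = [equilibrium_pitch(invivo_geometry, default_material, d) for d in ds]
        assert all(b > a - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_quartic_stationarity_at_solution(self, default_material):
        """The returned pitch is a root of the stationarity polynomial."""
        for geom, mat, _ in fixture_generator(seed=7, n=25):
            d = 0.9 * geom.d0
            p = equilibrium_pitch(geom, mat, d)
            a0, a1, a2, a3, a4 = _quartic_coeffs(geom, mat, d)
            assert a2 == 0.0
            residual = a0 + a1 * p + a3 * p**3 + a4 * p**4
            assert abs(residual) / (abs(a4) * p**4) < 1e-6

    @pytest.mark.parametrize("d_factor", [0.0, -0.5, 1.01])
    def test_out_of_range_diameter_rejected(self, invivo_geometry, default_material, d_factor):
        with pytest.raises(ValidationError):
            equilibrium_pitch(invivo_geometry, default_material, d_factor * invivo_geometry.d0)


class TestContactLineForce:
    def test_zero_at_unloaded_diameter(self, paper_geometries, default_material):
        for g in paper_geometries:
            assert contact_line_force(g, default_material, g.d0) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_matches_virtual_work_oracle(self, invivo_geometry, default_material):
        g, m = invivo_geometry, default_material
        for ratio in (0.99, 0.95, 0.9, 0.8):
            f = contact_line_force(g, m, ratio * g.d0)
            assert f == pytest.approx(
                virtual_work_force_oracle(g, m, ratio * g.d0), rel=1e-3
            )

    def test_linear_in_elastic_modulus(self, invivo_geometry):
        d = 0.92 * invivo_geometry.d0
        f1 = contact_line_force(invivo_geometry, WireMaterial(E=75e9), d)
        f2 = contact_line_force(invivo_geometry, WireMaterial(E=150e9), d)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-13)


class TestPressureForDiameter:
    def test_zero_at_unloaded_diameter(self, invivo_geometry, default_material):
        assert pressure_for_diameter(
            invivo_geometry, default_material, invivo_geometry.d0
        ) == pytest.approx(0.0, abs=1e-9)

    def test_strictly_increasing_under_compression(
        self, paper_geometries, default_material
    ):
        """Supported pressure grows monotonically as the stent narrows."""
        for g in paper_geometries:
            ds = np.linspace(g.d0, 0.7 * g.d0, 100)
            rhos = [pressure_for_diameter(g, default_material, d) for d in ds]
            assert all(b > a for a, b in zip(rhos, rhos[1:]))

    def test_continuous_limit_at_unloaded_diameter(
        self, invivo_geometry, default_material
    ):
        g, m = invivo_geometry, default_material
        rho_near = pressure_for_diameter(g, m, (1.0 - 1e-8) * g.d0)
        assert rho_near < 0.01  # Pa; vanishes continuously, no jump
        p_near = equilibrium_pitch(g, m, (1.0 - 1e-8) * g.d0)
        assert p_near == pytest.approx(g.p0, rel=1e-6)


class TestDiameterUnderPressure:
    def test_zero_pressure_is_identity(self, invivo_geometry, default_material):
        s = diameter_under_pressure(invivo_geometry, default_material, 0.0)
        assert s.d == invivo_geometry.d0
        assert s.p == pytest.approx(invivo_geometry.p0, rel=1e-9)
        assert s.energy == 0.0
        assert s.area_ratio == 1.0

    def test_all_design_geometries_compress_at_10_cmH2O(
        self, paper_geometries, default_material
    ):
        for g in paper_geometries:
            s = diameter_under_pressure(g, default_material, 10 * CMH2O_TO_PA)
            assert 0.0 < s.d < g.d0
            assert s.p > g.p0
            assert 0.0 < s.area_ratio < 1.0

    def test_roundtrip_with_pressure_for_diameter(
        self, invivo_geometry, default_material
    ):
        for rho in (0.5, 2.0, 10.0, 20.0):
            s = diameter_under_pressure(
                invivo_geometry, default_material, rho * CMH2O_TO_PA
            )
            back = pressure_for_diameter(invivo_geometry, default_material, s.d)
            assert back == pytest.approx(rho * CMH2O_TO_PA, rel=1e-8)

    def test_doubling_pressure_and_stiffness_leaves_diameter_unchanged(
        self, invivo_geometry
    ):
        s1 = diameter_under_pressure(invivo_geometry, WireMaterial(E=75e9), 980.665)
        s2 = diameter_under_pressure(invivo_geometry, WireMaterial(E=150e9), 2 * 980.665)
        assert s2.d == pytest.approx(s1.d, rel=1e-10)

    def test_negative_pressure_rejected(self, invivo_geometry, default_material):
        with pytest.raises(ValidationError):
            diameter_under_pressure(invivo_geometry, default_material, -1.0)

    def test_inverts_tabulated_forward_curve(self, default_material):
        """Cross-check the inverse against interpolation of the forward map."""
        g = paper_geometry(0.38, 23.0)
        ds = np.linspace(g.d0, 0.75 * g.d0, 400)
        rhos = np.array([pressure_for_diameter(g, default_material, d) for d in ds])
        for rho in (3.0 * CMH2O_TO_PA, 10.0 * CMH2O_TO_PA):
            d_interp = np.interp(rho, rhos, ds)
            s = diameter_under_pressure(g, default_material, rho)
            assert s.d == pytest.approx(d_interp, rel=1e-4)


class TestPressureSweep:
    def test_shape_and_identity_first_row(self, invivo_geometry, default_material):
        curve = pressure_sweep(invivo_geometry, default_material, 10 * CMH2O_TO_PA, 11)
        assert len(curve) == 11
        assert curve.states[0].area_ratio == 1.0
        ratios = [s.area_ratio for s in curve]
        assert all(b <= a for a, b in zip(ratios, ratios[1:]))

    def test_refinement_consistency(self, invivo_geometry, default_material):
        """A denser sweep reproduces the coarse sweep at shared pressures."""
        coarse = pressure_sweep(invivo_geometry, default_material, 10 * CMH2O_TO_PA, 11)
        fine = pressure_sweep(invivo_geometry, default_material, 10 * CMH2O_TO_PA, 101)
        for i, s in enumerate(coarse):
            s_fine = fine.states[10 * i]
            assert s_fine.d == pytest.approx(s.d, rel=1e-9)

    def test_frame_columns_and_units(self, invivo_geometry, default_material):
        frame = pressure_sweep(
            invivo_geometry, default_material, 10 * CMH2O_TO_PA, 5
        ).to_frame()
        assert list(frame.columns) == [
            "pressure_cmH2O", "pressure_Pa", "diameter_mm", "pitch_mm",
            "helix_angle_deg", "area_ratio", "line_force_N_per_m", "energy_J",
        ]
        assert frame["pressure_cmH2O"].iloc[-1] == pytest.approx(10.0, rel=1e-9)
        assert frame["diameter_mm"].iloc[0] == pytest.approx(13.21, rel=1e-9)

    @pytest.mark.parametrize("rho_max, n", [(-1.0, 5), (0.0, 5), (100.0, 1)])
    def test_invalid_sweep_parameters_rejected(
        self, invivo_geometry, default_material, rho_max, n
    ):
        with pytest.raises(ValidationError):
            pressure_sweep(invivo_geometry, default_material, rho_max, n)
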