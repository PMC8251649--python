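import math

import numpy as np
import pytest
from mitodose.media import Medium, medium_lookup, mitochondrion_medium
from mitodose.multilayer import ETA0
from mitodose.scenes import Scene, build_model, voxelize
from mitodose.solver import (
    SolverOptions,
    absorbed_power,
    born_solve,
    cdm_solve,
    default_spacing,
    extinction_power,
    incident_field_3d,
    scattered_field,
    scattered_field_at,
    scattered_power_farfield,
)

from oracles import mie_efficiencies

LAM = 980e-9
UM = 1e-6


class TestIncidentField:
    def test_lateral_invariance(self, profile980):
        pts = np.array([[0.0, 0.0, 4.9995e-3], [3e-6, -2e-6, 4.9995e-3]])
        E, H = incident_field_3d(profile980, pts, "y")
        assert np.allclose(E[0], E[1])
        assert np.allclose(H[0], H[1])

    def test_consistency_with_1d_profile(self, profile980):
        z = -1e-9
        E, _ = incident_field_3d(profile980, np.array([[0.0, 0.0, z]]), "y")
        E1, _ = profile980.field_at(z)
        assert abs(np.linalg.norm(E[0]) - abs(E1)) / abs(E1) < 1e-12

    def test_polarization_directions_carry_downward_flux(self, profile980):
        pts = np.array([[0.0, 0.0, 2e-3]])
        for pol, e_ax in (("x", 0), ("y", 1)):
            E, H = incident_field_3d(profile980, pts, pol)
            assert abs(E[0, e_ax]) > 0
            assert abs(E[0, 1 - e_ax]) == 0
            sz = 0.5 * np.real(np.cross(E[0], np.conj(H[0])))[2]
            assert sz > 0

    def test_rejects_mito_stack(self, profile980_mito):
        with pytest.raises(ValueError, match="without a mito layer"):
            incident_field_3d(profile980_mito, np.zeros((1, 3)), "y")


class TestBornMode:
    def test_zero_contrast_field_equals_incident(self, profile980):
        scene = build_model("isolated", LAM,
                           mito_medium=medium_lookup("saline", LAM))
        grid = voxelize(scene, 100e-9)
        E, H = incident_field_3d(profile980, grid.positions, "y")
        f = born_solve(grid, E, H)
        assert np.array_equal(f.E, E)

    def test_cdm_zero_contrast_recovers_incident(self, profile980):
        scene = build_model("isolated", LAM,
                           mito_medium=medium_lookup("saline", LAM))
        grid = voxelize(scene, 100e-9)
        E, H = incident_field_3d(profile980, grid.positions, "y")
        f = cdm_solve(grid, E, H)
        assert np.max(np.abs(f.E - E)) / np.max(np.abs(E)) < 1e-10

    def test_cdm_approaches_born_at_small_contrast(self, profile980):
        devs = []
        for n_real in (1.36, 1.344, 1.332):
            med = Medium("weak", LAM, n_real,
                         medium_lookup("saline", LAM).n_imag)
            scene = build_model("isolated", LAM, mito_medium=med)
            grid = voxelize(scene, 100e-9)
            E, H = incident_field_3d(profile980, grid.positions, "y")
            fb = born_solve(grid, E, H)
            fc = cdm_solve(grid, E, H)
            devs.append(np.max(np.abs(fc.E - fb.E)) / np.max(np.abs(fb.E)))
        # the correction Born drops is first order in the contrast, so the
        # deviation must vanish linearly with it (uniformly over voxels)
        assert devs[2] < devs[1] < devs[0]
        assert devs[1] / devs[0] == pytest.approx(0.5, rel=0.2)
        assert devs[2] / devs[1] == pytest.approx(0.25, rel=0.2)

    def test_born_vs_cdm_dose_at_max_contrast(self, profile980):
        """The Born internal field stays within a few percent of the full
        solution at the top of the index range (weak-scatterer premise)."""
        med = mitochondrion_medium(LAM, 1.45, 85.0)
        scene = build_model("isolated", LAM, mito_medium=med)
        grid = voxelize(scene, default_spacing(LAM, 1.45))
        E, H = incident_field_3d(profile980, grid.positions, "y")
        fb, fc = born_solve(grid, E, H), cdm_solve(grid, E, H)
        vb = np.mean(np.sum(np.abs(fb.E) ** 2, axis=1))
        vc = np.mean(np.sum(np.abs(fc.E) ** 2, axis=1))
        assert abs(vb - vc) / vc < 0.07


class TestMieOracle:
    def test_absorbed_power_within_2pct(self, mie_sphere_solution):
        f, E0 = mie_sphere_solution
        nb, R = 1.328, 0.5e-6
        n_im = 85.0 * LAM / (4 * math.pi)
        qext, qsca, qabs = mie_efficiencies(
            complex(1.40 / nb, n_im / nb), 2 * math.pi * nb * R / LAM
        )
        intensity = 0.5 * E0**2 / (ETA0 / nb)
        p_mie = qabs * intensity * math.pi * R**2
        assert absorbed_power(f) == pytest.approx(p_mie, rel=0.02)

    def test_optical_theorem_power_balance(self, mie_sphere_solution):
        """Extinction equals scattering (far-field quadrature) plus
        absorption for the dipole solution."""
        f, _ = mie_sphere_solution
        p_ext = extinction_power(f)
        p_abs = absorbed_power(f)
        p_sca = scattered_power_farfield(f)
        assert p_abs + p_sca == pytest.approx(p_ext, rel=0.01)

    def test_extinction_within_2pct_of_mie(self, mie_sphere_solution):
        f, E0 = mie_sphere_solution
        nb, R = 1.328, 0.5e-6
        n_im = 85.0 * LAM / (4 * math.pi)
        qext, _, _ = mie_efficiencies(
            complex(1.40 / nb, n_im / nb), 2 * math.pi * nb * R / LAM
        )
        intensity = 0.5 * E0**2 / (ETA0 / nb)
        assert extinction_power(f) == pytest.approx(
            qext * intensity * math.pi * R**2, rel=0.02
        )


class TestScatteredField:
    def test_difference_definition(self):
        tot = np.ones((5, 3), complex)
        inc = np.full((5, 3), 0.25 + 0j)
        assert np.allclose(scattered_field(tot, inc), 0.75)
        with pytest.raises(ValueError, match="mismatched"):
            scattered_field(tot, inc[:3])

    def test_no_scatterer_no_scattered_field(self, profile980):
        scene = Scene([], medium_lookup("saline", LAM))
        grid = voxelize(scene, 100e-9)
        E = np.zeros((0, 3), complex)
        f = born_solve(grid, E, E)
        pts = np.array([[0.0, 0.0, 4.9995e-3]])
        assert np.allclose(scattered_field_at(f, pts), 0.0)

    def test_lateral_decay(self, isolated980):
        """|Es| beyond the body decays laterally; at 2.5 lambda0 it is
        below 10% of the in-body maximum."""
        f = isolated980.internal
        es_in = np.linalg.norm(
            scattered_field(f.E, f.E_inc), axis=1
        ).max()
        z = 4.9995e-3
        xs = np.array([2.0e-6, 2.8e-6, 4.0e-6])  # beyond the 1.5 um half-length
        pts = np.c_[xs, np.zeros(3), np.full(3, z)]
        es = np.linalg.norm(scattered_field_at(f, pts), axis=1)
        assert es[2] < es[1] < es[0]
        assert es[2] < 0.1 * es_in

    def test_first_order_linearity_in_contrast(self, profile980):
        """Scaling the permittivity contrast by s scales Es by ~s."""
        sal = medium_lookup("saline", LAM)
        es = {}
        for s, n_real in ((1.0, 1.35), (0.5, (1.35 + sal.n_real) / 2)):
            med = Medium("scaled", LAM, n_real, sal.n_imag)
            scene = build_model("isolated", LAM, mito_medium=med)
            grid = voxelize(scene, 100e-9)
            E, H = incident_field_3d(profile980, grid.positions, "y")
            f = cdm_solve(grid, E, H)
            pts = np.array([[2.5e-6, 0.0, 4.9995e-3]])
            es[s] = np.linalg.norm(scattered_field_at(f, pts))
        # contrast eps-eps_b scales by ~s (slightly nonlinear in n)
        eps = lambda n: n**2 - sal.n_real**2
        expected = eps((1.35 + sal.n_real) / 2) / eps(1.35)
        assert es[0.5] / es[1.0] == pytest.approx(expected, rel=0.05)


class TestConvergenceAndDeterminism:
    def test_grid_halving_changes_dose_below_1pct(self, profile980, isolated980):
        """Volume-averaged |E|^2 in the central mitochondrion moves by
        less than 1% when the default spacing is halved."""
        v_def = np.mean(np.sum(np.abs(isolated980.internal.E) ** 2, axis=1))
        scene = build_model("isolated", LAM)
        grid = voxelize(scene, default_spacing(LAM, 1.40) / 2)
        E, H = incident_field_3d(profile980, grid.positions, "y")
        f = cdm_solve(grid, E, H)
        v_half = np.mean(np.sum(np.abs(f.E) ** 2, axis=1))
        assert abs(v_def - v_half) / v_half < 0.01

    def test_deterministic_resolve(self, profile980):
        scene = build_model("isolated", LAM)
        grid = voxelize(scene, 100e-9)
        E, H = incident_field_3d(profile980, grid.positions, "y")
        f1 = cdm_solve(grid, E, H)
        f2 = cdm_solve(grid, E, H)
        assert np.array_equal(f1.E, f2.E)

    def test_residual_recorded_below_tolerance(self, isolated980):
        f = isolated980.internal
        assert f.mode == "cdm"
        assert 0 < f.residual <= 1e-6
        assert f.iterations > 0

    def test_invalid_options(self):
        with pytest.raises(ValueError):
            SolverOptions(tolerance=0.5)
        with pytest.raises(ValueError):
            SolverOptions(mode="fem")


class TestWeakLateralInteraction:
    def test_seven_horizontal_close_to_isolated(self, isolated980):
        """Neighbor bodies in one horizontal layer shift the central dose
        by only a few percent (the premise that justifies small scenes)."""
        from mitodose.dosimetry import power_density_avg
        from mitodose.reporting import solve_preset

        pd_iso = isolated980.report.Pd[0]
        sm7 = solve_preset("seven_horizontal", LAM, sweep_fidelity=True)
        pd7 = sm7.report.Pd[0]
        assert abs(pd7 - pd_iso) / pd_iso < 0.03
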