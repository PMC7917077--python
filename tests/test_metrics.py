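"""ILT thickness, TAWSS, and Green-Lagrange strain operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rawindex import (face_deformation_gradient, green_lagrange,
                      ilt_thickness, max_principal_strain, tawss)
from rawindex.metrics import principal_strain, strain_from_tracking

from conftest import cylinder, rotation_matrix


class TestIltThickness:
    def test_coincident_meshes_zero(self):
        m = cylinder(radius=10.0, n_rings=11, n_circ=12)
        t = ilt_thickness(m, m, radius=4.0)
        assert np.allclose(t.thickness, 0.0)

    def test_concentric_cylinders_recover_gap(self):
        wall = cylinder(radius=13.0, n_rings=41, n_circ=48)
        lumen = cylinder(radius=10.0, n_rings=41, n_circ=48)
        t = ilt_thickness(wall, lumen, radius=4.0)
        ok = np.isfinite(t.thickness)
        assert ok.all()
        assert np.all(t.thickness >= 3.0 - 1e-12)   # never below the true gap
        assert np.all(np.abs(t.thickness[ok] - 3.0) < wall.mean_edge_length() / 2)

    def test_mean_method_never_below_nearest(self):
        wall = cylinder(radius=13.0, n_rings=21, n_circ=24)
        lumen = cylinder(radius=10.0, n_rings=21, n_circ=24)
        near = ilt_thickness(wall, lumen, 4.0, method="nearest").thickness
        mean = ilt_thickness(wall, lumen, 4.0, method="mean").thickness
        assert np.all(mean >= near - 1e-12)

    def test_doubling_radius_never_loses_neighbors(self):
        wall = cylinder(radius=13.0, n_rings=15, n_circ=16)
        lumen = cylinder(radius=10.0, n_rings=15, n_circ=16)
        n1 = ilt_thickness(wall, lumen, 4.0, method="mean").n_neighbors
        n2 = ilt_thickness(wall, lumen, 8.0, method="mean").n_neighbors
        assert np.all(n2 >= n1)

    def test_out_of_radius_is_missing_not_zero(self):
        wall = cylinder(radius=20.0, n_rings=11, n_circ=12)
        lumen = cylinder(radius=10.0, n_rings=11, n_circ=12)
        t = ilt_thickness(wall, lumen, radius=3.0)
        assert t.n_missing == wall.n_nodes

    def test_joint_rigid_motion_invariance(self):
        wall = cylinder(radius=13.0, n_rings=15, n_circ=16)
        lumen = cylinder(radius=10.0, n_rings=15, n_circ=16)
        base = ilt_thickness(wall, lumen, 4.0).thickness
        R, t = rotation_matrix([1, 1, 0], 1.1), np.array([5.0, -2.0, 7.0])
        moved = ilt_thickness(wall.transformed(R, t), lumen.transformed(R, t),
                              4.0).thickness
        assert np.allclose(base, moved, atol=1e-9)

    def test_invalid_radius_rejected(self):
        m = cylinder(n_rings=5, n_circ=8)
        with pytest.raises(ValueError, match="radius"):
            ilt_thickness(m, m, radius=0.0)


class TestTawss:
    def test_constant_magnitude_is_identity(self):
        w = np.ones((5, 7, 3)) / np.sqrt(3.0)   # |tau| = 1 Pa everywhere
        t = np.linspace(0.0, 0.8, 5)
        assert np.allclose(tawss(w, t), 1.0)

    def test_alternating_magnitudes_average_with_periodic_closure(self):
        # |tau| = 0, 2, 0, 2 at uniform spacing -> hand trapezoid gives 1 Pa
        mags = np.array([0.0, 2.0, 0.0, 2.0])
        w = np.zeros((4, 3, 3))
        w[:, :, 0] = mags[:, None]
        assert np.allclose(tawss(w, np.arange(4) * 0.25), 1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(6, 10, 3))
        t = np.sort(rng.uniform(0, 1, 6))
        assert np.allclose(tawss(3.5 * w, t), 3.5 * tawss(w, t))

    def test_uniform_spacing_reduces_to_arithmetic_mean(self):
        rng = np.random.default_rng(4)
        w = rng.normal(size=(8, 5, 3))
        t = np.arange(8) / 8.0
        assert np.allclose(tawss(w, t), np.linalg.norm(w, axis=2).mean(axis=0))

    def test_errors(self):
        w = np.ones((1, 2, 3))
        with pytest.raises(ValueError):
            tawss(w, np.array([0.0]))
        with pytest.raises(ValueError, match="increasing"):
            tawss(np.ones((3, 2, 3)), np.array([0.0, 0.5, 0.4]))


class TestDeformationGradient:
    ref = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.5, 1.5, 0]])

    def test_identity_for_identical_triangles(self):
        F = face_deformation_gradient(self.ref, self.ref)
        assert np.allclose(F, np.eye(2), atol=1e-12)

    def test_uniform_scaling_recovered(self):
        F = face_deformation_gradient(self.ref, 1.1 * self.ref)
        assert np.allclose(F, 1.1 * np.eye(2), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_rotation_gives_orthonormal_F(self, seed):
        rng = np.random.default_rng(seed)
        R = rotation_matrix(rng.normal(size=3), rng.uniform(0, np.pi))
        F = face_deformation_gradient(self.ref, self.ref @ R.T + rng.normal(size=3))
        assert np.allclose(F.T @ F, np.eye(2), atol=1e-12)

    def test_degenerate_triangle_rejected(self):
        bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            face_deformation_gradient(bad, bad)


class TestGreenLagrange:
    def test_identity_gives_zero_strain(self):
        E = green_lagrange(np.eye(2))
        assert np.allclose(E, 0.0)
        assert principal_strain(E) == pytest.approx(0.0)

    def test_equibiaxial_closed_form(self):
        E = green_lagrange(1.1 * np.eye(2))
        assert principal_strain(E) == pytest.approx(0.5 * (1.1**2 - 1), abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_rotation_strain_free(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 2 * np.pi)
        R2 = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        assert abs(principal_strain(green_lagrange(R2))) < 1e-12

    def test_objectivity_under_appended_rigid_motion(self):
        # E's eigenvalues unchanged when a rigid motion follows the stretch
        rng = np.random.default_rng(11)
        F = np.eye(2) + 0.05 * rng.normal(size=(2, 2))
        a = rng.uniform(0, 2 * np.pi)
        R2 = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        e1 = np.linalg.eigvalsh(green_lagrange(F))
        e2 = np.linalg.eigvalsh(green_lagrange(R2 @ F))
        assert np.allclose(e1, e2, atol=1e-10)

    def test_nonfinite_F_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            green_lagrange(np.array([[np.nan, 0], [0, 1.0]]))

    def test_cycle_maximum_over_phases(self):
        lams = np.array([1.0, 1.02, 1.05, 1.01])
        E = np.stack([green_lagrange(l * np.eye(2))[None] for l in lams])
        assert max_principal_strain(E)[0] == pytest.approx(0.5 * (1.05**2 - 1))


class TestStrainFromTracking:
    def test_rigid_body_cycle_is_strain_free(self, small_aaa):
        wall = small_aaa.outer_wall
        phases = []
        for k in range(4):
            R = rotation_matrix([0, 1, 1], 0.2 * k)
            phases.append(wall.nodes @ R.T + np.array([1.0, 2.0, 3.0]) * k)
        res = strain_from_tracking(wall, np.stack(phases))
        assert np.all(np.abs(res.max_principal) < 1e-10)

    def test_recovers_planted_truth(self, small_aaa):
        res = strain_from_tracking(small_aaa.outer_wall,
                                   small_aaa.phase_positions)
        assert np.allclose(res.max_principal,
                           small_aaa.truth_max_principal_strain, atol=1e-8)

    def test_shape_mismatch_rejected(self, small_aaa):
        with pytest.raises(ValueError, match="phase_positions"):
            strain_from_tracking(small_aaa.outer_wall,
                                 small_aaa.phase_positions[:, :-1, :])
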