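"""Centerline extraction, 24-patch parcellation, and regional averaging."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rawindex import (PatientAxes, assign_patches, compute_centerline,
                      patch_average)
from rawindex.patching import PatchAssignment

from conftest import cylinder, rotation_matrix, torus_tube


class TestCenterline:
    def test_straight_cylinder_centerline_on_axis(self):
        cl = compute_centerline(cylinder(radius=10.0), n_samples=20)
        assert np.all(np.abs(cl.points[:, :2]) < 1e-6)
        assert np.all(np.diff(cl.arclength) > 0)

    def test_translation_equivariance(self):
        cl = compute_centerline(cylinder(radius=10.0, origin=(5.0, 5.0, 0.0)),
                                n_samples=20)
        assert np.allclose(cl.points[:, 0], 5.0, atol=1e-6)
        assert np.allclose(cl.points[:, 1], 5.0, atol=1e-6)

    def test_curved_tube_tracks_analytic_arc(self):
        mesh, arc = torus_tube()
        cl = compute_centerline(mesh, n_samples=30)
        # distance of each recovered point to the parametric arc polyline
        d = np.min(np.linalg.norm(cl.points[:, None, :] - arc[None, :, :],
                                  axis=2), axis=1)
        assert d.max() < mesh.mean_edge_length() / 2

    def test_spans_inlet_to_outlet(self):
        cl = compute_centerline(cylinder(length=60.0), n_samples=40)
        assert cl.length > 0.9 * 60.0


@pytest.fixture(scope="module")
def wall_and_centerline():
    wall = cylinder(radius=12.0)
    return wall, compute_centerline(wall, n_samples=30)


class TestAssignPatches:

    def test_default_gives_24_nonempty_patches(self, wall_and_centerline):
        wall, cl = wall_and_centerline
        a = assign_patches(wall, cl)
        areas = a.patch_areas()
        assert len(areas) == 24
        assert (areas > 0).all()
        assert len(set(a.labels)) == 24

    def test_partition_area_conservation(self, wall_and_centerline):
        wall, cl = wall_and_centerline
        a = assign_patches(wall, cl)
        assert a.patch_areas().sum() == pytest.approx(wall.total_area(),
                                                      rel=1e-9)

    def test_quadrant_naming_convention(self, wall_and_centerline):
        wall, cl = wall_and_centerline
        a = assign_patches(wall, cl)
        c = wall.face_centroids()
        mid = (c[:, 2] > 20) & (c[:, 2] < 40)
        # DICOM LPS: left = +x, anterior = -y
        la = mid & (c[:, 0] > 1) & (c[:, 1] < -1)
        assert np.all(np.char.startswith(a.labels[la], "LA"))
        rp = mid & (c[:, 0] < -1) & (c[:, 1] > 1)
        assert np.all(np.char.startswith(a.labels[rp], "RP"))

    def test_rigid_motion_with_axes_is_invariant(self):
        # detuned azimuthally and axially so no centroid sits exactly on a
        # patch boundary (boundary ties are broken lexically, and a tie can
        # legitimately resolve differently after rotation round-off)
        wall = cylinder(radius=12.0, n_rings=32).transformed(
            rotation_matrix([0, 0, 1], 0.07))
        cl = compute_centerline(wall, n_samples=30)
        base = assign_patches(wall, cl)
        R = rotation_matrix([1, 2, 3], 0.7)
        t = np.array([3.0, -8.0, 12.0])
        wall2 = wall.transformed(R, t)
        from rawindex.patching import Centerline
        cl2 = Centerline(cl.points @ R.T + t)
        moved = assign_patches(wall2, cl2, axes=PatientAxes().rotated(R))
        assert np.array_equal(base.labels, moved.labels)

    def test_n_axial_configurable(self, wall_and_centerline):
        wall, cl = wall_and_centerline
        a = assign_patches(wall, cl, n_axial=3)
        assert len(a.patch_areas()) == 12

    def test_short_centerline_rejected(self, wall_and_centerline):
        wall, _ = wall_and_centerline
        from rawindex.patching import Centerline
        stub = Centerline(np.array([[0, 0, 25.0], [0, 0, 35.0]]))
        with pytest.raises(ValueError, match="shorter"):
            assign_patches(wall, stub)


class TestPatchAverage:
    def _two_face_assignment(self, areas):
        return PatchAssignment(face_axial=np.zeros(len(areas), dtype=int),
                               face_quadrant=np.array(["LA"] * len(areas)),
                               n_axial=1, face_areas=np.asarray(areas, float))

    def test_hand_computed_weighted_mean(self):
        a = self._two_face_assignment([1.0, 3.0])
        avg = patch_average(np.array([0.0, 4.0]), a)
        assert avg["LA1"] == pytest.approx(3.0)

    def test_constant_field_preserved(self, small_aaa):
        cl = compute_centerline(small_aaa.lumen, 30)
        a = assign_patches(small_aaa.outer_wall, cl)
        avg = patch_average(np.full(small_aaa.outer_wall.n_faces, 7.25), a)
        assert np.allclose(avg.to_numpy(), 7.25)

    def test_global_mean_conserved(self, small_aaa):
        cl = compute_centerline(small_aaa.lumen, 30)
        a = assign_patches(small_aaa.outer_wall, cl)
        rng = np.random.default_rng(0)
        v = rng.normal(size=small_aaa.outer_wall.n_faces)
        avg = patch_average(v, a)
        areas = a.patch_areas()
        global_from_patches = float((avg * areas).sum() / areas.sum())
        w = small_aaa.outer_wall.face_areas()
        assert global_from_patches == pytest.approx(float((v * w).sum() / w.sum()))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=st.floats(-10, 10), b=st.floats(-10, 10))
    def test_commutes_with_affine_transforms(self, a, b):
        assignment = self._two_face_assignment([1.0, 2.0, 3.0])
        v = np.array([1.0, -2.0, 0.5])
        direct = patch_average(a * v + b, assignment)["LA1"]
        composed = a * patch_average(v, assignment)["LA1"] + b
        assert direct == pytest.approx(composed, abs=1e-9)

    def test_missing_values_excluded_not_zeroed(self):
        a = self._two_face_assignment([1.0, 3.0])
        avg = patch_average(np.array([np.nan, 4.0]), a)
        assert avg["LA1"] == pytest.approx(4.0)

    def test_length_mismatch_raises(self, small_aaa):
        cl = compute_centerline(small_aaa.lumen, 30)
        a = assign_patches(small_aaa.outer_wall, cl)
        with pytest.raises(ValueError, match="match"):
            patch_average(np.ones(3), a)

    def test_all_missing_patch_yields_nan(self):
        a = self._two_face_assignment([1.0, 3.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            avg = patch_average(np.array([np.nan, np.nan]), a)
        assert np.isnan(avg["LA1"])
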