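import numpy as np
import pytest

from rawindex import SurfaceMesh, SyntheticAAAConfig, make_aaa
from rawindex.synthetic import _tube_faces


def tube_mesh(radius_fn, length=60.0, n_rings=31, n_circ=24, origin=(0, 0, 0)):
    """Structured open tube along z with radius_fn(z, theta) -> mm."""
    z = np.linspace(0.0, length, n_rings)
    theta = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    Z, TH = np.meshgrid(z, theta, indexing="ij")
    r = radius_fn(Z.ravel(), TH.ravel())
    pts = np.column_stack([r * np.cos(TH.ravel()), r * np.sin(TH.ravel()),
                           Z.ravel()]) + np.asarray(origin, dtype=float)
    return SurfaceMesh(pts, _tube_faces(n_rings, n_circ))


def cylinder(radius=10.0, **kw):
    return tube_mesh(lambda z, th: np.full_like(z, radius), **kw)


def torus_tube(arc_radius=100.0, tube_radius=10.0, arc_angle=1.2,
               n_rings=61, n_circ=24):
    """Tube bent along a circular arc in the x-z plane; returns (mesh,
    analytic centerline samples)."""
    phi = np.linspace(0.0, arc_angle, n_rings)
    theta = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    pts = []
    for p in phi:
        c = np.array([arc_radius * (1 - np.cos(p)), 0.0, arc_radius * np.sin(p)])
        # outward in-plane direction from the arc's center of curvature
        radial = np.array([-np.cos(p), 0.0, np.sin(p)])
        binorm = np.array([0.0, 1.0, 0.0])
        for t in theta:
            pts.append(c + tube_radius * (np.cos(t) * radial + np.sin(t) * binorm))
    mesh = SurfaceMesh(np.asarray(pts), _tube_faces(n_rings, n_circ))
    p_fine = np.linspace(0.0, arc_angle, 400)
    arc = np.column_stack([arc_radius * (1 - np.cos(p_fine)),
                           np.zeros_like(p_fine), arc_radius * np.sin(p_fine)])
    return mesh, arc


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


@pytest.fixture(scope="session")
def small_aaa_config():
    """Reduced-resolution AAA for fast end-to-end tests."""
    return SyntheticAAAConfig(n_axial_rings=25, n_circ=24, n_phases=10, seed=42)


@pytest.fixture(scope="session")
def small_aaa(small_aaa_config):
    return make_aaa(small_aaa_config)
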