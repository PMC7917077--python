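"""Regional wall descriptors: ILT thickness, TAWSS, and principal strain.

Three per-element fields feed the RAW index:

* **ILT thickness** — for every outer-wall node, the mean distance to the
  lumen-surface nodes lying within a search radius; the gap is the
  intraluminal thrombus layer.
* **TAWSS** — time-averaged wall-shear-stress magnitude over one cardiac
  cycle, ``(1/T) \\int |tau(t)| dt`` per face, trapezoidal with periodic
  closure.
* **Maximum principal Green-Lagrange strain** — from the in-plane
  deformation gradient of each tracked triangle, ``E = (F^T F - I)/2``,
  largest eigenvalue, maximised over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

DEFAULT_ILT_RADIUS_MM = 5.0


# ---------------------------------------------------------------------------
# ILT thickness


@dataclass
class ThicknessField:
    """Per-node ILT thickness (mm); NaN where no lumen node fell inside the
    search radius (missing, deliberately not zero)."""

    thickness: np.ndarray
    search_radius: float
    n_neighbors: np.ndarray | None = None   # per node, 'mean' method only

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.thickness)))


def ilt_thickness(wall: SurfaceMesh, lumen: SurfaceMesh,
                  radius: float = DEFAULT_ILT_RADIUS_MM,
                  method: str = "nearest") -> ThicknessField:
    """Thrombus thickness at each outer-wall node from its lumen-surface
    neighborhood, node-to-node, bounded by a search ``radius`` (mm).

    Methods
    -------
    ``'nearest'`` (default)
        Distance to the closest lumen node inside the radius. Unbiased
        estimate of the wall-to-lumen gap (up to lumen mesh spacing).
    ``'mean'``
        Mean distance to *all* lumen nodes inside the radius. Included
        distances range from the gap up to the radius, so for gaps well
        below the radius this systematically over-reads the thickness by
        up to ~radius/2; use it only with a radius close to the expected
        thickness.
    ``'surface'``
        Distance to the nearest point on the lumen triangulation
        (point-to-triangle rather than node-to-node).

    Nodes with no lumen neighbor inside the radius are missing (NaN).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if lumen.n_nodes == 0:
        raise ValueError("empty lumen mesh")
    if method == "surface":
        _, dist, _ = lumen.to_trimesh().nearest.on_surface(wall.nodes)
        return ThicknessField(np.where(dist <= radius, dist, np.nan), radius)
    if method == "nearest":
        tree = cKDTree(lumen.nodes)
        dist, _ = tree.query(wall.nodes, distance_upper_bound=radius)
        return ThicknessField(np.where(np.isfinite(dist), dist, np.nan), radius)
    if method != "mean":
        raise ValueError(f"unknown method {method!r}")
    tree = cKDTree(lumen.nodes)
    neighbor_lists = tree.query_ball_point(wall.nodes, r=radius)
    t = np.full(wall.n_nodes, np.nan)
    counts = np.zeros(wall.n_nodes, dtype=int)
    for i, nb in enumerate(neighbor_lists):
        counts[i] = len(nb)
        if nb:
            t[i] = np.linalg.norm(lumen.nodes[nb] - wall.nodes[i], axis=1).mean()
    return ThicknessField(t, radius, counts)


def node_to_face(mesh: SurfaceMesh, node_values: np.ndarray) -> np.ndarray:
    """Per-face mean of a per-node field, ignoring NaN vertices (NaN only
    when all three vertices are missing)."""
    vals = np.asarray(node_values, dtype=float)[mesh.faces]
    ok = np.isfinite(vals)
    n = ok.sum(axis=1)
    s = np.where(ok, vals, 0.0).sum(axis=1)
    return np.where(n > 0, s / np.maximum(n, 1), np.nan)


# ---------------------------------------------------------------------------
# TAWSS


def tawss(wss_vectors: np.ndarray, phase_times: np.ndarray,
          period: float | None = None) -> np.ndarray:
    """Time-averaged WSS magnitude per face.

    ``wss_vectors`` is (n_phases, n_faces, 3) in Pa (or (n_phases, n_faces)
    magnitudes); ``phase_times`` are the sample instants spanning one cycle.
    The integral closes periodically (last sample wraps to the first); the
    period defaults to the sample span plus one mean spacing, so uniform
    sampling reduces TAWSS to the arithmetic mean of the magnitudes.
    """
    w = np.asarray(wss_vectors, dtype=float)
    t = np.asarray(phase_times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need >= 2 phases")
    if np.any(np.diff(t) <= 0):
        raise ValueError("phase times must be strictly increasing")
    if w.shape[0] != len(t):
        raise ValueError("wss series and phase times disagree on phase count")
    mag = np.linalg.norm(w, axis=-1) if w.ndim == 3 else np.abs(w)
    if period is None:
        period = (t[-1] - t[0]) + float(np.mean(np.diff(t)))
    if period <= t[-1] - t[0]:
        raise ValueError("period must exceed the sampled span")
    t_closed = np.concatenate([t, [t[0] + period]])
    mag_closed = np.concatenate([mag, mag[:1]], axis=0)
    return np.trapezoid(mag_closed, t_closed, axis=0) / period


# ---------------------------------------------------------------------------
# Green-Lagrange strain from tracked triangles


@dataclass
class StrainResult:
    """Per-face strain over the tracked cycle."""

    F: np.ndarray                   # (n_phases, n_faces, 2, 2)
    E: np.ndarray                   # (n_phases, n_faces, 2, 2)
    principal: np.ndarray           # (n_phases, n_faces) largest eigenvalue of E
    max_principal: np.ndarray       # (n_faces,) cycle maximum


def _local_coords(tri: np.ndarray, area_tol: float = 1e-12) -> np.ndarray:
    """2D edge-vector coordinates of each triangle in its own orthonormal
    in-plane frame; tri is (..., 3, 3), result (..., 2, 2) with columns the
    two edge vectors from vertex 0."""
    e1 = tri[..., 1, :] - tri[..., 0, :]
    e2 = tri[..., 2, :] - tri[..., 0, :]
    n = np.cross(e1, e2)
    n_norm = np.linalg.norm(n, axis=-1)
    if np.any(n_norm <= 2 * area_tol):
        raise ValueError("degenerate triangle (area below tolerance)")
    u = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    w = n / n_norm[..., None]
    v = np.cross(w, u)
    # columns: [e1, e2] expressed in the (u, v) frame
    out = np.empty(tri.shape[:-2] + (2, 2))
    out[..., 0, 0] = np.einsum("...i,...i->...", e1, u)
    out[..., 1, 0] = np.einsum("...i,...i->...", e1, v)
    out[..., 0, 1] = np.einsum("...i,...i->...", e2, u)
    out[..., 1, 1] = np.einsum("...i,...i->...", e2, v)
    return out


def face_deformation_gradient(ref_triangle: np.ndarray,
                              def_triangle: np.ndarray) -> np.ndarray:
    """In-plane 2x2 deformation gradient mapping the reference triangle's
    edge vectors (in its local frame) onto the deformed ones (in theirs).

    Vectorised: accepts (..., 3, 3) stacks of triangles with vertex
    correspondence and returns (..., 2, 2).
    """
    A = _local_coords(np.asarray(ref_triangle, dtype=float))
    B = _local_coords(np.asarray(def_triangle, dtype=float))
    return B @ np.linalg.inv(A)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange tensor ``E = (F^T F - I) / 2`` (batched)."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite deformation gradient")
    FtF = np.swapaxes(F, -1, -2) @ F
    return 0.5 * (FtF - np.eye(F.shape[-1]))


def max_principal_strain(E: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of each symmetric strain tensor; if a leading
    phase axis is present, also maximised over it.

    For input (n_phases, n_faces, 2, 2) returns (n_faces,); for
    (..., 2, 2) without a phase axis use ``principal_strain``.
    """
    p = principal_strain(E)
    return p.max(axis=0) if p.ndim >= 1 and E.ndim >= 4 else p


def principal_strain(E: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of each symmetric 2x2 (or 3x3) tensor."""
    return np.linalg.eigvalsh(E)[..., -1]


def strain_from_tracking(mesh: SurfaceMesh, phase_positions: np.ndarray,
                         reference_phase: int = 0) -> StrainResult:
    """Per-face strain history from tracked nodal positions.

    ``phase_positions`` is (n_phases, n_nodes, 3); phase ``reference_phase``
    is the undeformed configuration.  The per-face cycle maximum of the
    largest principal strain is taken before any regional averaging.
    """
    pos = np.asarray(phase_positions, dtype=float)
    if pos.ndim != 3 or pos.shape[1] != mesh.n_nodes or pos.shape[2] != 3:
        raise ValueError("phase_positions must be (n_phases, n_nodes, 3) "
                         "matching the mesh")
    ref_tri = mesh.triangles(pos[reference_phase])
    n_phases = pos.shape[0]
    F = np.empty((n_phases, mesh.n_faces, 2, 2))
    for k in range(n_phases):
        F[k] = face_deformation_gradient(ref_tri, mesh.triangles(pos[k]))
    E = green_lagrange(F)
    princ = principal_strain(E)
    return StrainResult(F=F, E=E, principal=princ, max_principal=princ.max(axis=0))
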