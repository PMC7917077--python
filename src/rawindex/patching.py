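"""Lumen centerline extraction and 24-patch parcellation of the aortic wall.

The wall is partitioned into a sampling grid of axial sections crossed with
circumferential quadrants: by default 6 equal-arclength stations along the
lumen centerline x 4 quadrants (left/right x anterior/posterior), giving the
24 regions used both for intra-operative sample tracking and for regional
averaging of the hemodynamic and kinematic descriptors.

Quadrant naming follows radiological convention: LA = left anterior,
RP = right posterior, etc. Patient axes default to DICOM LPS (left = +x,
posterior = +y, superior = +z); pass a :class:`PatientAxes` to override.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh

QUADRANTS = ("LA", "LP", "RA", "RP")


@dataclass
class PatientAxes:
    """Anatomical direction vectors in mesh coordinates (unit, orthogonal)."""

    left: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    posterior: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        for v in (self.left, self.posterior):
            n = np.linalg.norm(v)
            if not np.isclose(n, 1.0, atol=1e-8):
                raise ValueError("axes must be unit vectors")
        if abs(self.left @ self.posterior) > 1e-8:
            raise ValueError("axes must be orthogonal")

    @property
    def anterior(self) -> np.ndarray:
        return -self.posterior

    def rotated(self, rotation: np.ndarray) -> "PatientAxes":
        R = np.asarray(rotation, dtype=float)
        return PatientAxes(R @ self.left, R @ self.posterior)


@dataclass
class Centerline:
    """Ordered polyline through the lumen with cumulative arclength (mm)."""

    points: np.ndarray
    arclength: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("centerline needs >= 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline arclength must be strictly increasing")
        self.arclength = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, self.arclength, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)


def compute_centerline(lumen: SurfaceMesh, n_samples: int = 60,
                       n_refine: int = 2, smooth_window: int = 0) -> Centerline:
    """Centerline as the ordered centroids of cross-sections cut
    perpendicular to the (iteratively re-estimated) local vessel axis.

    A first marching pass slices perpendicular to the lumen's principal
    axis (PCA of the node cloud) at ``n_samples`` interior stations
    (half-step inset so open rims do not produce empty cuts); a section
    that falls apart into multiple loops there indicates branching and
    raises. ``n_refine`` further passes re-slice perpendicular to the
    current centerline tangent at arclength-uniform stations, which removes
    the oblique-section bias on curved vessels; if such a plane also cuts a
    distant part of the tube the loop nearest the station is kept.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    pts = lumen.nodes
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    axis = vt[0]
    proj = (pts - center) @ axis
    lo, hi = proj.min(), proj.max()
    tm = lumen.to_trimesh()

    step = (hi - lo) / n_samples
    stations = lo + (np.arange(n_samples) + 0.5) * step
    centroids = []
    for s in stations:
        origin = center + s * axis
        sec = tm.section(plane_origin=origin, plane_normal=axis)
        if sec is None or len(sec.vertices) == 0:
            raise ValueError(f"lumen not sliceable at station {s:.2f} mm")
        if len(sec.entities) > 1:
            raise ValueError(f"branching cross-section at station {s:.2f} mm "
                             f"({len(sec.entities)} loops)")
        centroids.append(np.asarray(sec.vertices, dtype=float).mean(axis=0))
    centroids = np.asarray(centroids)
    if (centroids[-1] - centroids[0]) @ axis < 0:
        centroids = centroids[::-1]

    for _ in range(max(n_refine, 0)):
        cl = Centerline(centroids)
        s_uniform = np.linspace(cl.arclength[0], cl.arclength[-1], n_samples)
        points = np.column_stack([
            np.interp(s_uniform, cl.arclength, cl.points[:, i])
            for i in range(3)])
        tangents = np.column_stack([
            np.interp(s_uniform, cl.arclength, cl.tangents()[:, i])
            for i in range(3)])
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        edges = tm.edges_unique
        refined = []
        for origin, normal in zip(points, tangents):
            cross = _plane_crossings(lumen.nodes, edges, origin, normal)
            if len(cross) < 3:
                continue                   # grazing cut beyond the rim
            cluster = _nearest_cluster(cross, origin)
            if not _loop_is_closed(cluster, normal):
                continue                   # partial arc: plane exits an open end
            refined.append(cluster.mean(axis=0))
        if len(refined) < 2:
            break
        centroids = np.asarray(refined)

    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(centroids, ((pad, pad), (0, 0)), mode="edge")
        centroids = np.column_stack(
            [np.convolve(padded[:, i], kernel, mode="valid")[: len(centroids)]
             for i in range(3)])
    return Centerline(centroids)


@dataclass
class PatchAssignment:
    """Face -> patch map over ``n_axial x 4`` patches.

    Patch labels are quadrant + 1-based axial index, e.g. ``LA2`` (left
    anterior, second station from the inlet).
    """

    face_axial: np.ndarray       # 0-based axial bin per face
    face_quadrant: np.ndarray    # {LA, LP, RA, RP} per face
    n_axial: int
    face_areas: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.char.add(self.face_quadrant.astype("U2"),
                                  (self.face_axial + 1).astype("U8"))

    @property
    def patch_ids(self) -> list[str]:
        """All patch labels in (axial, quadrant) order."""
        return [f"{q}{i + 1}" for i in range(self.n_axial) for q in QUADRANTS]

    def patch_areas(self) -> pd.Series:
        areas = pd.Series(0.0, index=self.patch_ids)
        sums = pd.Series(self.face_areas).groupby(self.labels).sum()
        areas[sums.index] = sums
        return areas

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "face_id": np.arange(len(self.labels)),
            "axial": self.face_axial + 1,
            "quadrant": self.face_quadrant,
            "patch": self.labels,
            "area_mm2": self.face_areas,
        })


def assign_patches(wall: SurfaceMesh, centerline: Centerline, n_axial: int = 6,
                   axes: PatientAxes | None = None,
                   resample: int = 400) -> PatchAssignment:
    """Assign every wall face to an axial-station x quadrant patch.

    Each face centroid maps to its nearest point on a densely resampled
    centerline; the arclength there picks one of ``n_axial`` equal-arclength
    bins, and the sign of the centroid's offset from the centerline along the
    patient left and anterior axes picks the quadrant.  Ties on a quadrant
    boundary go to the left / anterior labels.
    """
    if n_axial < 1:
        raise ValueError("n_axial must be >= 1")
    axes = axes or PatientAxes()
    s_fine = np.linspace(0.0, centerline.length, resample)
    fine = np.column_stack([
        np.interp(s_fine, centerline.arclength, centerline.points[:, i])
        for i in range(3)])
    tree = cKDTree(fine)
    centroids = wall.face_centroids()
    _, idx = tree.query(centroids)
    s = s_fine[idx]

    extent = _axial_extent(wall, centerline)
    if centerline.length < 0.8 * extent:
        raise ValueError(
            f"centerline ({centerline.length:.1f} mm) much shorter than the "
            f"wall's axial extent ({extent:.1f} mm)")

    axial = np.minimum((s / centerline.length * n_axial).astype(int), n_axial - 1)
    offset = centroids - fine[idx]
    left = offset @ axes.left >= 0.0
    anterior = offset @ axes.anterior >= 0.0
    quadrant = np.char.add(np.where(left, "L", "R"), np.where(anterior, "A", "P"))

    assignment = PatchAssignment(axial, quadrant, n_axial, wall.face_areas())
    empty = [p for p, a in assignment.patch_areas().items() if a == 0.0]
    if empty:
        warnings.warn(f"empty patches: {', '.join(empty)}", stacklevel=2)
    return assignment


def patch_average(values: np.ndarray, assignment: PatchAssignment) -> pd.Series:
    """Area-weighted mean of a per-face field over each patch.

    Missing (NaN) faces are excluded from both numerator and weight; a patch
    with no contributing area yields NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != assignment.face_areas.shape:
        raise ValueError(f"field length {values.shape} does not match "
                         f"face count {assignment.face_areas.shape}")
    ok = np.isfinite(values)
    w = np.where(ok, assignment.face_areas, 0.0)
    num = pd.Series(w * np.where(ok, values, 0.0)).groupby(assignment.labels).sum()
    den = pd.Series(w).groupby(assignment.labels).sum()
    out = pd.Series(np.nan, index=assignment.patch_ids)
    avg = num / den.replace(0.0, np.nan)
    out[avg.index] = avg
    return out


def _plane_crossings(nodes: np.ndarray, edges: np.ndarray, origin: np.ndarray,
                     normal: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Points where mesh edges cross a plane (vertices lying in the plane
    count once); robust when the plane coincides with a mesh ring."""
    d = (nodes - origin) @ normal
    on_plane = np.abs(d) <= tol
    da, db = d[edges[:, 0]], d[edges[:, 1]]
    straddle = (da * db < 0) & ~on_plane[edges[:, 0]] & ~on_plane[edges[:, 1]]
    t = da[straddle] / (da[straddle] - db[straddle])
    pts = nodes[edges[straddle, 0]] + t[:, None] * (
        nodes[edges[straddle, 1]] - nodes[edges[straddle, 0]])
    return np.vstack([pts, nodes[on_plane]]) if on_plane.any() else pts


def _nearest_cluster(points: np.ndarray, origin: np.ndarray,
                     gap_factor: float = 2.0) -> np.ndarray:
    """Points belonging to the cross-section loop nearest the origin: sorted
    by distance, the cluster ends at the first multiplicative gap (a distant
    second cut of the same plane through a curved tube)."""
    dist = np.linalg.norm(points - origin, axis=1)
    order = np.argsort(dist)
    ds = dist[order]
    jumps = np.nonzero(ds[1:] > gap_factor * np.maximum(ds[:-1], 1e-12))[0]
    keep = order[: jumps[0] + 1] if len(jumps) else order
    return points[keep]


def _loop_is_closed(points: np.ndarray, normal: np.ndarray,
                    max_gap_deg: float = 60.0) -> bool:
    """True when the cross-section points wrap all the way around their
    centroid (largest angular gap below ``max_gap_deg``)."""
    u = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(normal, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    d = points - points.mean(axis=0)
    ang = np.sort(np.arctan2(d @ v, d @ u))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.degrees(gaps.max())) <= max_gap_deg


def _axial_extent(wall: SurfaceMesh, centerline: Centerline) -> float:
    direction = centerline.points[-1] - centerline.points[0]
    direction = direction / np.linalg.norm(direction)
    proj = wall.nodes @ direction
    return float(proj.max() - proj.min())
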