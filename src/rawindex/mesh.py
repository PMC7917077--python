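"""Triangulated surface meshes with attached per-node / per-face fields.

The two geometries this package works on — the aortic lumen and the outer
aortic wall — are open tube-like triangulated surfaces in millimetres,
typically segmented from CT. :class:`SurfaceMesh` is a thin validated
container over node coordinates and triangle connectivity; heavy geometric
queries (cross-sections, spatial indexing) are delegated to ``trimesh`` and
``scipy.spatial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


@dataclass
class SurfaceMesh:
    """A triangulated surface with optional scalar/vector data arrays.

    Parameters
    ----------
    nodes : (n_nodes, 3) float array
        Node coordinates in millimetres.
    faces : (n_faces, 3) int array
        Triangles as node-index triplets.
    node_data, face_data : dict of str -> array
        Fields attached to nodes or faces. First dimension must match the
        node / face count; extra dimensions (e.g. vectors) are allowed.
    """

    nodes: np.ndarray
    faces: np.ndarray
    node_data: dict[str, np.ndarray] = field(default_factory=dict)
    face_data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self, area_tol: float = 1e-12) -> None:
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError(f"nodes must be (n, 3), got {self.nodes.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.nodes)):
            raise ValueError("face indices out of range")
        areas = self.face_areas()
        if np.any(areas <= area_tol):
            bad = int(np.sum(areas <= area_tol))
            raise ValueError(f"{bad} degenerate (zero-area) faces")
        for name, arr in {**self.node_data}.items():
            if len(arr) != len(self.nodes):
                raise ValueError(f"node field {name!r} has length {len(arr)}, expected {len(self.nodes)}")
        for name, arr in {**self.face_data}.items():
            if len(arr) != len(self.faces):
                raise ValueError(f"face field {name!r} has length {len(arr)}, expected {len(self.faces)}")

    # -- geometry --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Per-face (m, 3, 3) vertex coordinates, optionally at alternative
        nodal positions (same connectivity)."""
        pos = self.nodes if positions is None else np.asarray(positions, dtype=float)
        return pos[self.faces]

    def face_areas(self, positions: np.ndarray | None = None) -> np.ndarray:
        tri = self.triangles(positions)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_centroids(self, positions: np.ndarray | None = None) -> np.ndarray:
        return self.triangles(positions).mean(axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def mean_edge_length(self) -> float:
        tri = self.triangles()
        e = np.concatenate([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]])
        return float(np.linalg.norm(e, axis=1).mean())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.nodes.copy(), self.faces.copy(), process=False)

    def transformed(self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None) -> "SurfaceMesh":
        """Rigidly transformed copy (fields carried over unchanged)."""
        pts = self.nodes
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return SurfaceMesh(pts, self.faces.copy(),
                           {k: np.array(v) for k, v in self.node_data.items()},
                           {k: np.array(v) for k, v in self.face_data.items()})

    # -- I/O -------------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path) -> "SurfaceMesh":
        """Load a surface from STL/PLY/OFF/OBJ (via trimesh) or legacy VTK."""
        path = Path(path)
        if path.suffix.lower() == ".vtk":
            return _read_legacy_vtk(path)
        tm = trimesh.load_mesh(str(path), process=False)
        if isinstance(tm, trimesh.Scene):
            tm = tm.to_mesh()
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64))

    def write(self, path: str | Path) -> None:
        """Write STL/PLY/OFF (geometry only, via trimesh) or legacy-ASCII
        VTK POLYDATA carrying all attached data arrays."""
        path = Path(path)
        if path.suffix.lower() == ".vtk":
            write_legacy_vtk(path, self)
        else:
            self.to_trimesh().export(str(path))


def write_legacy_vtk(path: str | Path, mesh: SurfaceMesh, comment: str = "rawindex surface") -> None:
    """Write a legacy-ASCII VTK POLYDATA file with POINT_DATA / CELL_DATA
    scalar and 3-vector arrays — readable by ParaView and VTK."""
    lines = ["# vtk DataFile Version 3.0", comment[:255], "ASCII", "DATASET POLYDATA"]
    lines.append(f"POINTS {mesh.n_nodes} double")
    lines.extend(" ".join(f"{v:.10g}" for v in p) for p in mesh.nodes)
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines.extend(f"3 {a} {b} {c}" for a, b, c in mesh.faces)

    def _emit(data: dict[str, np.ndarray], n: int, kind: str) -> None:
        if not data:
            return
        lines.append(f"{kind} {n}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            safe = name.replace(" ", "_")
            if arr.ndim == 1:
                lines.append(f"SCALARS {safe} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {safe} double")
                lines.extend(" ".join(f"{v:.10g}" for v in row) for row in arr)
            else:
                raise ValueError(f"cannot write field {name!r} of shape {arr.shape}")

    _emit(mesh.node_data, mesh.n_nodes, "POINT_DATA")
    _emit(mesh.face_data, mesh.n_faces, "CELL_DATA")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_legacy_vtk(path: Path) -> SurfaceMesh:
    """Minimal reader for the POLYDATA files written by :func:`write_legacy_vtk`."""
    tok = path.read_text().split("\n")
    i = 0
    nodes = faces = None
    node_data: dict[str, np.ndarray] = {}
    face_data: dict[str, np.ndarray] = {}
    target = node_data
    while i < len(tok):
        line = tok[i].strip()
        parts = line.split()
        if line.startswith("POINTS"):
            n = int(parts[1])
            nodes = np.array([tok[i + 1 + k].split() for k in range(n)], dtype=float)
            i += n
        elif line.startswith("POLYGONS"):
            m = int(parts[1])
            faces = np.array([tok[i + 1 + k].split()[1:] for k in range(m)], dtype=np.int64)
            i += m
        elif line.startswith("POINT_DATA"):
            target = node_data
        elif line.startswith("CELL_DATA"):
            target = face_data
        elif line.startswith("SCALARS"):
            name = parts[1]
            n = len(nodes) if target is node_data else len(faces)
            vals = np.array(tok[i + 2:i + 2 + n], dtype=float)  # skip LOOKUP_TABLE
            target[name] = vals
            i += n + 1
        elif line.startswith("VECTORS"):
            name = parts[1]
            n = len(nodes) if target is node_data else len(faces)
            target[name] = np.array([tok[i + 1 + k].split() for k in range(n)], dtype=float)
            i += n
        i += 1
    if nodes is None or faces is None:
        raise ValueError(f"{path}: not a POLYDATA VTK file")
    return SurfaceMesh(nodes, faces, node_data, face_data)
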