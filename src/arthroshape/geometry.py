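"""Surface-mesh domain types and preprocessing operations.

Bone surfaces segmented from weightbearing CT arrive as triangulated PLY
meshes in millimetres, posed in the scanner frame. This module provides the
:class:`SurfaceMesh` container plus the surface-side preprocessing the
joint analyses need: left-to-right mirroring, Taubin smoothing with quadric
decimation, exact plane clipping (open boundary), and unsigned
surface-to-surface distance maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from ._decimate import decimate
from ._ply import read_ply, write_ply
from ._proximity import SurfaceProximity

BONE_LABELS = ("tibia", "fibula", "talus", "synthetic")
SIDES = ("left", "right", "n/a")


@dataclass
class SurfaceMesh:
    """Triangulated bone surface in mm with orientation metadata.

    Faces are counter-clockwise when seen from outside the bone, so the
    right-handed face normal points outward.
    """

    vertices: np.ndarray
    faces: np.ndarray
    bone_label: str = "synthetic"
    side: str = "n/a"
    subject_id: str = ""
    scalars: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.bone_label not in BONE_LABELS:
            raise ValueError(f"unknown bone_label {self.bone_label!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if not np.isfinite(self.vertices).all():
            raise ValueError("non-finite vertex coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                    | (f[:, 0] == f[:, 2])).any():
                raise ValueError("face repeats a vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    def copy(self) -> "SurfaceMesh":
        return replace(self, vertices=self.vertices.copy(),
                       faces=self.faces.copy(), scalars=dict(self.scalars))

    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", v[:, 0],
                               np.cross(v[:, 1], v[:, 2])).sum() / 6.0)

    def is_closed(self) -> bool:
        return self.to_trimesh().is_watertight

    def face_normals(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        norms = np.linalg.norm(n, axis=1)
        norms[norms == 0] = 1.0
        return n / norms[:, None]

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals."""
        v = self.vertices[self.faces]
        fn = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        return vn / norms[:, None]

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on an open boundary (edge used once)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[uniq[counts == 1].ravel()] = True
        return mask


@dataclass
class Plane:
    """Oriented cutting plane; geometry on the normal side is discarded."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("plane normal must be nonzero")
            self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class RigidTransform:
    """Proper rigid (optionally similarity) transform: x ↦ scale·R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.scale = float(self.scale)

    def validate(self) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is a reflection (det < 0)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points) @ self.rotation.T) + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.scale * (other.translation @ self.rotation.T)
                              + self.translation,
                              self.scale * other.scale)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -(rinv @ self.translation) / self.scale,
                              1.0 / self.scale)

    def to_json(self) -> str:
        return json.dumps({"rotation": self.rotation.tolist(),
                           "translation": self.translation.tolist(),
                           "scale": self.scale})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.array(d["rotation"]), np.array(d["translation"]),
                   d["scale"])


# ---------------------------------------------------------------------------
# mesh I/O

def load_mesh(path, expected_units: str = "mm", bone_label: str = "synthetic",
              side: str = "n/a", subject_id: str = "",
              triangulate_quads: bool = False) -> SurfaceMesh:
    """Load a PLY surface (ascii or binary little-endian), mm units assumed.

    Normals stored in the file are ignored; orientation is always recomputed
    from the winding. Quads are fan-triangulated when ``triangulate_quads``
    is set and rejected otherwise.
    """
    if expected_units != "mm":
        raise ValueError("units are fixed to millimetres; no unit inference")
    vertices, faces, scalars = read_ply(path, triangulate=triangulate_quads)
    mesh = SurfaceMesh(vertices, faces, bone_label=bone_label, side=side,
                       subject_id=subject_id, scalars=scalars)
    mesh.validate()
    return mesh


def save_mesh(mesh: SurfaceMesh, path, dialect: str = "binary_le",
              scalars: dict | None = None) -> None:
    """Write a PLY file, optionally with per-vertex scalar properties."""
    mesh.validate()
    write_ply(path, mesh.vertices, mesh.faces, dialect=dialect,
              scalars=scalars)


def save_scalars_csv(path, values: np.ndarray, name: str = "value") -> None:
    """Per-vertex scalar export as ``vertex_id,<name>`` CSV."""
    with open(path, "w") as fh:
        fh.write(f"vertex_id,{name}\n")
        for i, v in enumerate(np.asarray(values).ravel()):
            fh.write(f"{i},{v:.12g}\n")


def save_vtk_polydata(path, mesh: SurfaceMesh,
                      scalars: dict | None = None) -> None:
    """Legacy ascii VTK PolyData export for visualization tools."""
    scalars = scalars or {}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\narthroshape surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if scalars:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, vals in scalars.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in np.asarray(vals).ravel():
                    fh.write(f"{x:.12g}\n")


# ---------------------------------------------------------------------------
# geometric operations

_FLIP_SIDE = {"left": "right", "right": "left", "n/a": "n/a"}


def reflect_mesh(mesh: SurfaceMesh, mirror_axis: int = 0) -> SurfaceMesh:
    """Mirror a bone across the plane normal to ``mirror_axis`` (YZ plane by
    default, x → −x), reversing face winding so the outward orientation is
    preserved, and flipping the side metadata."""
    out = mesh.copy()
    out.vertices[:, mirror_axis] *= -1.0
    out.faces = out.faces[:, ::-1].copy()
    out.side = _FLIP_SIDE[mesh.side]
    return out


def preprocess_mesh(mesh: SurfaceMesh, smoothing_iterations: int = 10,
                    smoothing_factor: float = 0.5,
                    target_face_count: int | None = None) -> SurfaceMesh:
    """Taubin smoothing (volume-preserving) followed by quadric decimation.

    ``smoothing_factor`` is the Taubin λ; the shrink-compensation step uses
    μ = −0.53. ``target_face_count=None`` skips decimation.
    """
    mesh.validate()
    if target_face_count is not None and target_face_count < 4:
        raise ValueError("target_face_count must be >= 4")
    tm = mesh.to_trimesh()
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(tm, lamb=smoothing_factor, nu=0.53,
                                        iterations=smoothing_iterations)
    vertices, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    if target_face_count is not None and len(faces) > target_face_count:
        vertices, faces = decimate(vertices, faces, target_face_count)
    # drop zero-area faces left by degenerate input
    v = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
    faces = faces[areas > 1e-12]
    out = replace(mesh, vertices=np.asarray(vertices, dtype=np.float64),
                  faces=np.asarray(faces, dtype=np.int64), scalars={})
    out.validate()
    return out


def clip_mesh(mesh: SurfaceMesh, plane: Plane) -> SurfaceMesh:
    """Exact plane clip: faces crossing the plane are cut at edge–plane
    intersections; the part on the plane's normal side is discarded and the
    boundary is left open (not capped)."""
    mesh.validate()
    sd = plane.signed_distance(mesh.vertices)
    if (sd <= 1e-12).all():
        return mesh.copy()
    if (sd >= -1e-12).all():
        return replace(mesh, vertices=np.zeros((0, 3)),
                       faces=np.zeros((0, 3), dtype=np.int64), scalars={})
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=-plane.normal,
        plane_origin=plane.point, cap=False)
    out = replace(mesh, vertices=np.asarray(sliced.vertices, dtype=np.float64),
                  faces=np.asarray(sliced.faces, dtype=np.int64), scalars={})
    out.validate()
    return out


def surface_to_surface_distance(mesh_a: SurfaceMesh,
                                mesh_b: SurfaceMesh) -> np.ndarray:
    """Unsigned closest-point distance (point-to-triangle) from every vertex
    of ``mesh_a`` to the surface of ``mesh_b``, in mm."""
    mesh_a.validate()
    mesh_b.validate()
    if mesh_b.n_faces == 0:
        raise ValueError("target mesh has no faces")
    prox = SurfaceProximity(mesh_b.vertices, mesh_b.faces)
    dist, _, _ = prox.query(mesh_a.vertices)
    return dist
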