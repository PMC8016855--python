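"""Discrete per-vertex curvature with a bone-outward sign convention.

Mean curvature H comes from the cotangent mean-curvature normal with mixed
Voronoi vertex areas (Meyer et al.), signed by projection onto the outward
vertex normal so convex bone regions have H > 0 (a sphere of radius r gives
H = +1/r; a socket gives −1/r). Gaussian curvature G is the angle defect
over the same area. Principal curvatures follow from the quadratic
relation K² − 2HK + G = 0:

    K_min = H − √(H² − G),   K_max = H + √(H² − G),

with the discriminant clamped at zero (and flagged) where the discrete
estimates violate H² ≥ G. ``second principal curvature`` means K_min, the
algebraically smaller value — concave articular sockets carry K_min < 0,
which is what articular-region seeding thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SurfaceMesh


@dataclass
class CurvatureField:
    """Per-vertex H (mm⁻¹), G (mm⁻²), principal curvatures, and flags."""

    H: np.ndarray
    G: np.ndarray
    kmin: np.ndarray
    kmax: np.ndarray
    clamped: np.ndarray
    boundary: np.ndarray

    def validate(self) -> None:
        if (self.kmin > self.kmax + 1e-12).any():
            raise ValueError("kmin exceeds kmax")
        ok = ~self.clamped
        if not np.allclose(self.H[ok], (self.kmin[ok] + self.kmax[ok]) / 2,
                           atol=1e-9):
            raise ValueError("H != (kmin + kmax)/2 on unclamped vertices")
        if not np.allclose(self.G[ok], self.kmin[ok] * self.kmax[ok],
                           atol=1e-9):
            raise ValueError("G != kmin*kmax on unclamped vertices")


def principal_from_HG(H, G, tol: float = 1e-9):
    """Principal curvatures from mean and Gaussian curvature.

    Returns ``(kmin, kmax, clamped)`` with the discriminant H² − G clamped
    at zero; ``clamped`` marks vertices where it was more negative than
    ``tol`` (discrete estimates need not satisfy H² ≥ G).
    """
    H = np.asarray(H, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    disc = H * H - G
    clamped = disc < -tol
    root = np.sqrt(np.maximum(disc, 0.0))
    return H - root, H + root, clamped


def second_principal_curvature(field: CurvatureField) -> np.ndarray:
    """The algebraically smaller principal curvature, K_min."""
    return field.kmin


def angle_defects(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex angle defect: 2π − Σ incident angles (π − Σ on boundary).

    Summed over a closed mesh this is exactly 2π·χ (Gauss–Bonnet).
    """
    v = mesh.vertices
    f = mesh.faces
    angle_sum = np.zeros(mesh.n_vertices)
    for k in range(3):
        a = v[f[:, k]]
        b = v[f[:, (k + 1) % 3]]
        c = v[f[:, (k + 2) % 3]]
        u1 = b - a
        u2 = c - a
        cosang = np.einsum("ij,ij->i", u1, u2) / (
            np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1))
        np.add.at(angle_sum, f[:, k], np.arccos(np.clip(cosang, -1.0, 1.0)))
    boundary = mesh.boundary_vertices()
    defect = 2.0 * np.pi - angle_sum
    defect[boundary] = np.pi - angle_sum[boundary]
    return defect


def _mixed_voronoi_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Meyer et al. mixed Voronoi vertex areas (obtuse-safe)."""
    v = mesh.vertices
    f = mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    areas_f = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)

    corners = [(p0, p1, p2), (p1, p2, p0), (p2, p0, p1)]
    cot = np.empty((len(f), 3))
    for k, (a, b, c) in enumerate(corners):
        u1, u2 = b - a, c - a
        cross = np.linalg.norm(np.cross(u1, u2), axis=1)
        cot[:, k] = np.einsum("ij,ij->i", u1, u2) / np.maximum(cross, 1e-300)

    obtuse_any = (cot < 0).any(axis=1)
    area_v = np.zeros(mesh.n_vertices)
    # edge opposite corner k joins corners k+1, k+2; Voronoi contribution
    # at vertex k is (|e_j|² cot(at the vertex opposite e_j)) / 8 for the
    # two edges incident to k
    e2 = np.stack([((p1 - p2) ** 2).sum(axis=1),
                   ((p2 - p0) ** 2).sum(axis=1),
                   ((p0 - p1) ** 2).sum(axis=1)], axis=1)  # e2[:,k] opp. k
    for k in range(3):
        j1, j2 = (k + 1) % 3, (k + 2) % 3
        voronoi = (e2[:, j1] * cot[:, j1] + e2[:, j2] * cot[:, j2]) / 8.0
        contrib = np.where(
            obtuse_any,
            np.where(cot[:, k] < 0, areas_f / 2.0, areas_f / 4.0),
            voronoi)
        np.add.at(area_v, f[:, k], contrib)
    return area_v


def curvature_field(mesh: SurfaceMesh) -> CurvatureField:
    """Estimate H, G and principal curvatures at every vertex.

    Requires consistent winding; boundary vertices are computed but flagged
    unreliable (region seeding excludes them by default).
    """
    mesh.validate()
    _check_winding(mesh)
    v = mesh.vertices
    f = mesh.faces
    area = _mixed_voronoi_areas(mesh)
    area = np.maximum(area, 1e-300)

    # cotangent mean-curvature normal: K(x_i) = Σ (cotα+cotβ)(x_i − x_j)/(2A)
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    corners = [(p0, p1, p2), (p1, p2, p0), (p2, p0, p1)]
    cot = np.empty((len(f), 3))
    for k, (a, b, c) in enumerate(corners):
        u1, u2 = b - a, c - a
        cross = np.linalg.norm(np.cross(u1, u2), axis=1)
        cot[:, k] = np.einsum("ij,ij->i", u1, u2) / np.maximum(cross, 1e-300)

    kvec = np.zeros_like(v)
    for k in range(3):
        i1, i2 = (k + 1) % 3, (k + 2) % 3  # edge (i1, i2) opposite corner k
        w = cot[:, k][:, None]
        diff = v[f[:, i1]] - v[f[:, i2]]
        np.add.at(kvec, f[:, i1], w * diff)
        np.add.at(kvec, f[:, i2], -w * diff)
    kvec /= (2.0 * area)[:, None]

    normals = mesh.vertex_normals()
    H = 0.5 * np.einsum("ij,ij->i", kvec, normals)

    defect = angle_defects(mesh)
    G = defect / area

    boundary = mesh.boundary_vertices()
    kmin, kmax, clamped = principal_from_HG(H, G)
    field = CurvatureField(H, G, kmin, kmax, clamped, boundary)
    return field


def _check_winding(mesh: SurfaceMesh) -> None:
    """Reject meshes whose interior edges are not consistently wound."""
    f = mesh.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    key = edges.min(axis=1).astype(np.int64) * (mesh.n_vertices + 1) \
        + edges.max(axis=1)
    order = np.argsort(key, kind="stable")
    sk = key[order]
    se = edges[order]
    same = np.flatnonzero(sk[:-1] == sk[1:])
    if len(same):
        # consistently wound interior edges appear once in each direction
        bad = (se[same, 0] == se[same + 1, 0])
        if bad.any():
            raise ValueError("inconsistent face winding")


def curvature_csv_rows(field: CurvatureField):
    return [{"vertex_id": i, "H": float(field.H[i]), "G": float(field.G[i]),
             "Kmin": float(field.kmin[i]), "Kmax": float(field.kmax[i]),
             "clamped": bool(field.clamped[i])}
            for i in range(len(field.H))]
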