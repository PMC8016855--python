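"""Exact point-to-triangle proximity and ray-triangle intersection.

Vectorized numpy implementations of the two spatial queries the joint
analyses rely on: unsigned closest-point distance from query points to a
triangle soup (used for joint-space distance and surface-distance maps) and
Möller–Trumbore ray casting (used for articular coverage). Candidate
triangles are pruned with a KD-tree over triangle centroids so the queries
stay near-linear for the mesh sizes segmented bones produce.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_triangles(points: np.ndarray, tri: np.ndarray):
    """Closest point on each of a set of triangles for each query point.

    points: (n, 3); tri: (m, 3, 3). Returns (dist2, closest) with shapes
    (n, m) and (n, m, 3).
    """
    p = points[:, None, :]
    return _closest_point_core(p, tri[None, :, 0, :], tri[None, :, 1, :],
                               tri[None, :, 2, :])


def _closest_point_rows(points: np.ndarray, tri: np.ndarray):
    """Per-row candidates: points (n, 3) against tri (n, kk, 3, 3)."""
    p = points[:, None, :]
    return _closest_point_core(p, tri[:, :, 0, :], tri[:, :, 1, :],
                               tri[:, :, 2, :])


def _closest_point_core(p, a, b, c):
    """Region-classified point-triangle projection (Ericson, Real-Time
    Collision Detection §5.1.5), broadcast over the last-but-one axis."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ac, ap)[0], ap)
    bp = p - b
    d3 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ac, bp)[0], bp)
    cp = p - c
    d5 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ab, cp)[0], cp)
    d6 = np.einsum("nmk,nmk->nm", np.broadcast_arrays(ac, cp)[0], cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom != 0, vb / denom, 0.0)
        w_face = np.where(denom != 0, vc / denom, 0.0)
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        w_bc_num = d4 - d3
        w_bc_den = (d4 - d3) + (d5 - d6)
        w_bc = np.where(w_bc_den != 0, w_bc_num / w_bc_den, 0.0)

    closest = a + v_face[..., None] * ab + w_face[..., None] * ac  # interior default

    region_a = (d1 <= 0) & (d2 <= 0)
    region_b = (d3 >= 0) & (d4 <= d3)
    region_c = (d6 >= 0) & (d5 <= d6)
    region_ab = (~region_a) & (~region_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    region_ac = (~region_a) & (~region_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    region_bc = (~region_b) & (~region_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    closest = np.where(region_bc[..., None],
                       b + np.clip(w_bc, 0, 1)[..., None] * (c - b), closest)
    closest = np.where(region_ac[..., None],
                       a + np.clip(w_ac, 0, 1)[..., None] * ac, closest)
    closest = np.where(region_ab[..., None],
                       a + np.clip(v_ab, 0, 1)[..., None] * ab, closest)
    closest = np.where(region_c[..., None], np.broadcast_to(c, closest.shape), closest)
    closest = np.where(region_b[..., None], np.broadcast_to(b, closest.shape), closest)
    closest = np.where(region_a[..., None], np.broadcast_to(a, closest.shape), closest)

    diff = p - closest
    dist2 = np.einsum("nmk,nmk->nm", diff, diff)
    return dist2, closest


class SurfaceProximity:
    """Closest-point queries against a fixed triangle mesh.

    Prunes with a centroid KD-tree: the distance to the nearest centroid
    plus that triangle's circumradius bounds the true closest distance, and
    every triangle whose centroid ball could beat the bound is tested
    exactly.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise ValueError("proximity query against a mesh with no faces")
        self.tri = self.vertices[self.faces]
        self.centroids = self.tri.mean(axis=1)
        self.radii = np.linalg.norm(
            self.tri - self.centroids[:, None, :], axis=2).max(axis=1)
        self.max_radius = float(self.radii.max())
        self._tree = cKDTree(self.centroids)

    _CHUNK_PAIRS = 200_000  # bound on (points × candidate triangles) temporaries

    def query(self, points: np.ndarray, k_candidates: int = 64):
        """Return (distances, closest_points, face_indices) for each point.

        Each point is tested exactly against its ``k_candidates`` nearest
        triangles (by centroid); when the pruning bound cannot certify the
        result (distant points, coarse meshes) the point falls back to an
        exact test against every triangle.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(points)
        m = len(self.tri)
        kk = min(k_candidates, m)
        d_cent, i_cent = self._tree.query(points, k=kk)
        d_cent = d_cent.reshape(n, kk)
        i_cent = i_cent.reshape(n, kk)

        dist, closest, fidx = self._batched_min(points, i_cent)
        if kk < m:
            # unseen triangles have centroid distance ≥ d_cent[:, -1], hence
            # surface distance ≥ that minus the largest triangle radius
            unsafe = dist > d_cent[:, -1] - self.max_radius + 1e-12
            if unsafe.any():
                idx = np.flatnonzero(unsafe)
                all_tri = np.broadcast_to(np.arange(m), (len(idx), m))
                d2, c2, f2 = self._batched_min(points[idx], all_tri)
                dist[idx], closest[idx], fidx[idx] = d2, c2, f2
        return dist, closest, fidx

    def _batched_min(self, points, cand):
        """Exact minimum over per-point candidate triangle index rows."""
        n, kk = cand.shape
        dist = np.empty(n)
        closest = np.empty((n, 3))
        fidx = np.empty(n, dtype=np.int64)
        rows_per_chunk = max(1, self._CHUNK_PAIRS // max(kk, 1))
        for s in range(0, n, rows_per_chunk):
            e = min(n, s + rows_per_chunk)
            block = cand[s:e]
            tri = self.tri[block]            # (rows, kk, 3, 3)
            p = points[s:e]
            d2, cp = _closest_point_rows(p, tri)
            j = np.argmin(d2, axis=1)
            r = np.arange(e - s)
            dist[s:e] = np.sqrt(d2[r, j])
            closest[s:e] = cp[r, j]
            fidx[s:e] = block[r, j]
        return dist, closest, fidx


def ray_triangle_hits(origins: np.ndarray, directions: np.ndarray,
                      tri: np.ndarray, max_length: float = np.inf,
                      eps: float = 1e-12):
    """First-hit ray casting (Möller–Trumbore) against a triangle soup.

    Returns (hit, t_hit, face_index): per-ray boolean, distance along the
    (unit) direction, and index of the nearest intersected triangle within
    ``max_length`` (−1 where no hit). Rays starting exactly on a triangle
    count a hit only for t > eps.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    n_rays = len(origins)
    m = len(tri)
    hit = np.zeros(n_rays, dtype=bool)
    t_best = np.full(n_rays, np.inf)
    f_best = np.full(n_rays, -1, dtype=np.int64)
    if m == 0:
        return hit, t_best, f_best

    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    # chunk over rays to bound the (rays × faces) temporaries
    chunk = max(1, int(4e6 // max(m, 1)))
    for s in range(0, n_rays, chunk):
        o = origins[s:s + chunk][:, None, :]
        d = directions[s:s + chunk][:, None, :]
        pvec = np.cross(d, e2[None, :, :])
        det = np.einsum("nmk,mk->nm", pvec, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = np.where(np.abs(det) > eps, 1.0 / det, 0.0)
        tvec = o - v0[None, :, :]
        u = np.einsum("nmk,nmk->nm", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("nmk,nmk->nm", np.broadcast_arrays(d, qvec)[0], qvec) * inv_det
        t = np.einsum("nmk,nmk->nm", qvec, np.broadcast_to(e2[None], qvec.shape)) * inv_det
        valid = ((np.abs(det) > eps) & (u >= -1e-9) & (v >= -1e-9)
                 & (u + v <= 1 + 1e-9) & (t > 1e-9) & (t <= max_length))
        t_masked = np.where(valid, t, np.inf)
        j = np.argmin(t_masked, axis=1)
        rows = np.arange(len(j))
        tmin = t_masked[rows, j]
        got = np.isfinite(tmin)
        hit[s:s + chunk] = got
        t_best[s:s + chunk] = np.where(got, tmin, np.inf)
        f_best[s:s + chunk] = np.where(got, j, -1)
    return hit, t_best, f_best
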