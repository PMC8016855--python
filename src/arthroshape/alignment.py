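"""Rigid and Procrustes alignment of bones and particle sets.

Cross-subject shape analysis needs every bone in a common frame: an
iterative-closest-point (ICP) registration with the talus as the reference
bone preserves each subject's weightbearing joint pose, a generalized
Procrustes analysis (GPA) then removes residual pose — and, when requested,
size — from the correspondence-particle sets, and a common cutting plane
standardizes the proximal extent of the shaft bones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._proximity import SurfaceProximity
from .geometry import Plane, RigidTransform, SurfaceMesh


def best_fit_rigid(source_points: np.ndarray, target_points: np.ndarray,
                   allow_scale: bool = False) -> RigidTransform:
    """Least-squares rigid (optionally similarity) transform source→target.

    Kabsch/Umeyama solution of min Σ‖s·R·x_i + t − y_i‖² with det(R) = +1
    enforced; reflections are never produced. Requires ≥ 3 non-collinear
    point pairs.
    """
    x = np.asarray(source_points, dtype=np.float64)
    y = np.asarray(target_points, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 point pairs")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    cov = xc.T @ yc / len(x)
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    if allow_scale:
        var_x = (xc ** 2).sum() / len(x)
        scale = float((s * np.diag(diag)).sum() / var_x)
    else:
        scale = 1.0
    trans = my - scale * (rot @ mx)
    return RigidTransform(rot, trans, scale)


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    converged: bool
    n_iterations: int


def icp_align(source_mesh: SurfaceMesh, target_mesh: SurfaceMesh,
              max_iterations: int = 50, rms_tolerance: float = 1e-6,
              init: RigidTransform | None = None, sample_count: int = 500,
              seed: int = 0) -> ICPResult:
    """Point-to-surface ICP aligning ``source_mesh`` onto ``target_mesh``.

    Source vertices are uniformly subsampled (seeded), matched to their
    closest points on the target surface, and a rigid fit is applied;
    iteration stops when the RMS improvement drops below ``rms_tolerance``
    or at ``max_iterations``. The RMS is non-increasing by construction;
    non-convergence returns the best transform found with
    ``converged=False``.
    """
    source_mesh.validate()
    target_mesh.validate()
    rng = np.random.default_rng(seed)
    pts = source_mesh.vertices
    if len(pts) > sample_count:
        idx = rng.choice(len(pts), size=sample_count, replace=False)
        idx.sort()
        pts = pts[idx]
    prox = SurfaceProximity(target_mesh.vertices, target_mesh.faces)
    face_normals = target_mesh.face_normals()

    transform = init if init is not None else RigidTransform.identity()
    moved = transform.apply(pts)
    dist, closest, fidx = prox.query(moved)
    rms = float(np.sqrt((dist ** 2).mean()))
    converged = False
    it = 0
    for it in range(1, max_iterations + 1):
        # try both a point-to-point and a linearized point-to-plane step,
        # keep whichever lowers the point-to-surface RMS most (monotone)
        candidates = [best_fit_rigid(moved, closest).compose(transform)]
        p2l = _point_to_plane_step(moved, closest, face_normals[fidx])
        if p2l is not None:
            candidates.append(p2l.compose(transform))
        best = None
        for cand in candidates:
            moved_c = cand.apply(pts)
            dist_c, closest_c, fidx_c = prox.query(moved_c)
            rms_c = float(np.sqrt((dist_c ** 2).mean()))
            if best is None or rms_c < best[0]:
                best = (rms_c, cand, moved_c, closest_c, fidx_c)
        rms_new, candidate, moved_new, closest_new, fidx_new = best
        if rms_new > rms + 1e-12:
            break  # safeguard: keep the monotone best
        improved = rms - rms_new
        transform, moved, closest, fidx, rms = (candidate, moved_new,
                                                closest_new, fidx_new, rms_new)
        if improved < rms_tolerance:
            converged = True
            break
    return ICPResult(transform, rms, converged, it)


def _point_to_plane_step(points, closest, normals) -> RigidTransform | None:
    """Small-angle point-to-plane rigid step (6×6 normal equations)."""
    c = np.cross(points, normals)
    a = np.hstack([c, normals])  # rows [p×n, n]
    b = -np.einsum("ij,ij->i", points - closest, normals)
    try:
        x, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    omega, trans = x[:3], x[3:]
    theta = np.linalg.norm(omega)
    if theta < 1e-15:
        rot = np.eye(3)
    else:
        k = omega / theta
        kmat = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(theta) * kmat + (1 - np.cos(theta)) * kmat @ kmat
    return RigidTransform(rot, trans, 1.0)


def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squares of coordinates about the centroid."""
    p = np.asarray(points, dtype=np.float64)
    return float(np.sqrt(((p - p.mean(axis=0)) ** 2).sum()))


def generalized_procrustes(particle_sets, remove_scale: bool = True,
                           tol: float = 1e-10, max_rounds: int = 200):
    """Generalized Procrustes analysis of index-matched particle sets.

    Each configuration is centred (and, with ``remove_scale``, normalized to
    unit centroid size), then iteratively rotated onto the evolving mean
    until the mean stops moving. Returns ``(aligned_sets, mean_set,
    per_subject_scale)`` where the scales are the original centroid sizes.
    """
    sets = [np.asarray(p, dtype=np.float64) for p in particle_sets]
    if len(sets) < 2:
        raise ValueError("GPA needs at least 2 particle sets")
    p0 = sets[0].shape
    if any(s.shape != p0 for s in sets):
        raise ValueError("particle count mismatch across sets")

    scales = np.array([centroid_size(s) for s in sets])
    aligned = []
    for s in sets:
        c = s - s.mean(axis=0)
        if remove_scale:
            c = c / centroid_size(c)
        aligned.append(c)

    # order-invariant initial mean; per-round updates are batchwise
    mean = np.mean(aligned, axis=0)
    if remove_scale and centroid_size(mean) > 0:
        mean = mean / centroid_size(mean)
    for _ in range(max_rounds):
        for i, a in enumerate(aligned):
            t = best_fit_rigid(a, mean, allow_scale=remove_scale)
            a2 = t.apply(a)
            a2 = a2 - a2.mean(axis=0)
            if remove_scale:
                a2 = a2 / centroid_size(a2)
            aligned[i] = a2
        new_mean = np.mean(aligned, axis=0)
        if remove_scale:
            n = centroid_size(new_mean)
            if n > 0:
                new_mean = new_mean / n
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    return aligned, mean, scales


def common_cutting_plane(aligned_meshes, axis=(0.0, 0.0, 1.0)) -> Plane:
    """Most proximal uniform plane present in all aligned specimens.

    The plane is perpendicular to the shaft ``axis`` and sits at the minimum
    over subjects of each subject's maximal extent along the axis, with the
    normal pointing proximal (so clipping discards the proximal shaft).
    """
    meshes = list(aligned_meshes)
    if not meshes:
        raise ValueError("empty mesh set")
    ax = np.asarray(axis, dtype=np.float64)
    ax = ax / np.linalg.norm(ax)
    level = min(float((m.vertices @ ax).max()) for m in meshes)
    return Plane(point=level * ax, normal=ax)
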