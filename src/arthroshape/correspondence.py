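"""Cross-subject correspondence-particle models.

A correspondence model places the same number of surface particles on every
subject's bone so that particle *i* marks the same anatomical location on
each specimen. Entropy-based particle-splitting optimizers (ShapeWorks
style) solve this with a population objective; the scheme here is a
deliberately simpler template-propagation model: farthest-point sampling on
a template subject, ICP-assisted projection onto every other subject, and
optional mean-reprojection rounds. It trades some correspondence quality
for transparency and determinism, which the synthetic oracles can verify.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import alignment
from ._proximity import SurfaceProximity
from ._tps import tps_warp
from .geometry import Plane, SurfaceMesh

DEFAULT_PARTICLES = 1024
SURFACE_TOLERANCE_MM = 0.5


def farthest_point_sample(points: np.ndarray, n_samples: int,
                          seed: int = 0,
                          candidate_mask: np.ndarray | None = None) -> np.ndarray:
    """Deterministic farthest-point sampling over a vertex set.

    Returns indices into ``points``. The first sample is drawn with the
    seeded generator; each subsequent sample maximizes the distance to the
    already-chosen set, which yields the hierarchical space-filling coverage
    that doubling particle counts refines.
    """
    pts = np.asarray(points, dtype=np.float64)
    if candidate_mask is None:
        cand = np.arange(len(pts))
    else:
        cand = np.flatnonzero(candidate_mask)
    if n_samples > len(cand):
        raise ValueError(
            f"requested {n_samples} particles but only {len(cand)} candidate vertices")
    rng = np.random.default_rng(seed)
    chosen = np.empty(n_samples, dtype=np.int64)
    chosen[0] = cand[rng.integers(len(cand))]
    d = np.linalg.norm(pts[cand] - pts[chosen[0]], axis=1)
    for k in range(1, n_samples):
        j = int(np.argmax(d))  # ties: lowest candidate index
        chosen[k] = cand[j]
        d = np.minimum(d, np.linalg.norm(pts[cand] - pts[chosen[k]], axis=1))
    return chosen


@dataclass
class CorrespondenceModel:
    """Ordered, cross-subject-matched particle arrays plus their mean.

    ``particles`` live in the common aligned frame on each subject's
    surface; ``aligned_particles`` are the GPA-aligned versions rescaled to
    the cohort-mean centroid size so they stay in millimetres, and
    ``mean_particles`` is their arithmetic mean.
    """

    subject_ids: list
    particles: dict
    mean_particles: np.ndarray
    aligned_particles: dict
    template_subject_id: str
    template_mesh: SurfaceMesh | None = None
    template_particle_vertices: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.mean_particles)

    def particle_matrix(self, aligned: bool = True) -> np.ndarray:
        src = self.aligned_particles if aligned else self.particles
        return np.stack([src[s] for s in self.subject_ids])

    def validate(self, meshes: dict | None = None,
                 surface_tolerance: float = SURFACE_TOLERANCE_MM) -> None:
        p = self.n_particles
        for s in self.subject_ids:
            if len(self.particles[s]) != p or len(self.aligned_particles[s]) != p:
                raise ValueError(f"particle count mismatch for subject {s}")
        recomputed = self.particle_matrix(aligned=True).mean(axis=0)
        if not np.allclose(recomputed, self.mean_particles, atol=1e-9):
            raise ValueError("mean_particles inconsistent with aligned sets")
        if meshes is not None:
            for s in self.subject_ids:
                prox = SurfaceProximity(meshes[s].vertices, meshes[s].faces)
                dist, _, _ = prox.query(self.particles[s])
                if dist.max() > surface_tolerance:
                    raise ValueError(
                        f"subject {s}: particle {int(np.argmax(dist))} is "
                        f"{dist.max():.3f} mm off-surface")

    # -- serialization (point-file convention: CSV per subject + manifest) --
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for s in self.subject_ids:
            for tag, arr in (("particles", self.particles[s]),
                             ("aligned", self.aligned_particles[s])):
                _write_particle_csv(directory / f"{s}.{tag}.csv", arr)
        _write_particle_csv(directory / "mean.particles.csv", self.mean_particles)
        manifest = {"subject_ids": list(self.subject_ids),
                    "template_subject_id": self.template_subject_id,
                    "n_particles": self.n_particles,
                    "provenance": self.provenance}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "CorrespondenceModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        subject_ids = manifest["subject_ids"]
        particles = {s: _read_particle_csv(directory / f"{s}.particles.csv")
                     for s in subject_ids}
        aligned = {s: _read_particle_csv(directory / f"{s}.aligned.csv")
                   for s in subject_ids}
        mean = _read_particle_csv(directory / "mean.particles.csv")
        return cls(subject_ids, particles, mean, aligned,
                   manifest["template_subject_id"],
                   provenance=manifest.get("provenance", {}))


def _write_particle_csv(path, arr) -> None:
    with open(path, "w") as fh:
        fh.write("particle_id,x,y,z\n")
        for i, (x, y, z) in enumerate(np.asarray(arr)):
            fh.write(f"{i},{x:.17g},{y:.17g},{z:.17g}\n")


def _read_particle_csv(path) -> np.ndarray:
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return rows[:, 1:4]


def select_template(meshes: dict, strategy: str = "medoid",
                    seed: int = 0) -> str:
    """Template subject: the medoid by summed pairwise light-ICP RMS."""
    ids = list(meshes)
    if strategy == "first" or len(ids) == 1:
        return ids[0]
    if strategy != "medoid":
        raise ValueError(f"unknown template strategy {strategy!r}")
    total = {}
    for i in ids:
        rms_sum = 0.0
        for j in ids:
            if i == j:
                continue
            res = alignment.icp_align(meshes[i], meshes[j], max_iterations=5,
                                      sample_count=100, seed=seed)
            rms_sum += res.rms
        total[i] = rms_sum
    return min(ids, key=lambda s: (total[s], s))


def build_correspondence_model(aligned_meshes: dict, P: int = DEFAULT_PARTICLES,
                               cutting_plane: Plane | None = None,
                               seed: int = 0, refine_rounds: int = 1,
                               template_strategy: str = "medoid",
                               remove_scale: bool = True,
                               icp_kwargs: dict | None = None
                               ) -> CorrespondenceModel:
    """Build a P-particle correspondence model over mutually aligned meshes.

    ``aligned_meshes`` maps subject_id → SurfaceMesh, all already ICP-aligned
    in one frame. Particles are farthest-point sampled on the template (only
    distal to ``cutting_plane`` when given), propagated to each subject by
    ICP plus closest-point projection, and optionally re-projected from the
    evolving mean for ``refine_rounds`` rounds. Deterministic under ``seed``.
    """
    ids = list(aligned_meshes)
    if not ids:
        raise ValueError("no meshes given")
    coarsest = min(m.n_vertices for m in aligned_meshes.values())
    if P > coarsest:
        raise ValueError(f"P={P} exceeds the coarsest mesh's {coarsest} vertices")
    icp_kwargs = dict(icp_kwargs or {})
    icp_kwargs.setdefault("seed", seed)

    template_id = select_template(aligned_meshes, template_strategy, seed=seed)
    template = aligned_meshes[template_id]

    mask = None
    if cutting_plane is not None:
        mask = cutting_plane.signed_distance(template.vertices) < 0
        if not mask.any():
            raise ValueError(
                f"subject {template_id}: no region distal to the cutting plane")
    seed_idx = farthest_point_sample(template.vertices, P, seed=seed,
                                     candidate_mask=mask)
    seed_points = template.vertices[seed_idx]

    prox = {}
    for s in ids:
        mesh = aligned_meshes[s]
        if cutting_plane is not None:
            if not (cutting_plane.signed_distance(mesh.vertices) < 0).any():
                raise ValueError(
                    f"subject {s}: no region distal to the cutting plane")
        prox[s] = SurfaceProximity(mesh.vertices, mesh.faces)

    particles = {}
    for s in ids:
        pts = seed_points
        if s != template_id:
            res = alignment.icp_align(template, aligned_meshes[s], **icp_kwargs)
            pts = res.transform.apply(seed_points)
        _, projected, _ = prox[s].query(pts)
        particles[s] = projected

    for _ in range(max(0, refine_rounds)):
        mean = np.mean([particles[s] for s in ids], axis=0)
        for s in ids:
            _, projected, _ = prox[s].query(mean)
            particles[s] = projected

    arrays = [particles[s] for s in ids]
    if len(ids) >= 2:
        aligned_sets, mean_unit, scales = alignment.generalized_procrustes(
            arrays, remove_scale=remove_scale)
        if remove_scale:
            # restore millimetres: cohort-mean centroid size, size variation gone
            mm = float(np.mean(scales))
            aligned_sets = [a * mm for a in aligned_sets]
            mean_particles = mean_unit * mm
        else:
            mean_particles = np.mean(aligned_sets, axis=0)
        # canonicalize the GPA frame onto the template pose (a global rigid
        # motion of a GPA solution is still a GPA solution); keeps the mean,
        # the aligned sets, and the template mesh in one frame
        canon = alignment.best_fit_rigid(mean_particles,
                                         particles[template_id])
        aligned_sets = [canon.apply(a) for a in aligned_sets]
        mean_particles = canon.apply(mean_particles)
        aligned = dict(zip(ids, aligned_sets))
    else:
        aligned = {ids[0]: arrays[0].copy()}
        mean_particles = arrays[0].copy()

    return CorrespondenceModel(
        subject_ids=ids, particles=particles,
        mean_particles=np.asarray(mean_particles),
        aligned_particles=aligned, template_subject_id=template_id,
        template_mesh=template,
        template_particle_vertices=seed_idx,
        provenance={"P": P, "seed": seed, "refine_rounds": refine_rounds,
                    "template_strategy": template_strategy,
                    "remove_scale": remove_scale})


def mean_shape(model: CorrespondenceModel):
    """Mean particle array and a mean surface.

    The template mesh is similarity-aligned onto the mean particles and then
    warped by thin-plate-spline interpolation of the residual template-
    particle → mean-particle displacements (exact at particle sites).
    """
    if model.template_mesh is None or model.template_particle_vertices is None:
        raise ValueError("model lacks template geometry")
    template_particles = model.particles[model.template_subject_id]
    t = alignment.best_fit_rigid(template_particles, model.mean_particles,
                                 allow_scale=True)
    moved_particles = t.apply(template_particles)
    moved_vertices = t.apply(model.template_mesh.vertices)
    disp = model.mean_particles - moved_particles
    if np.abs(disp).max(initial=0.0) < 1e-12:
        warped = moved_vertices
    else:
        warped = moved_vertices + tps_warp(moved_particles, disp, moved_vertices)
    surface = SurfaceMesh(warped, model.template_mesh.faces.copy(),
                          bone_label=model.template_mesh.bone_label,
                          side="n/a", subject_id="mean")
    return model.mean_particles.copy(), surface


def map_particles(mean_particles: np.ndarray, subject_mesh: SurfaceMesh,
                  mean_surface: SurfaceMesh | None = None,
                  icp_kwargs: dict | None = None):
    """Assign each mean-shape particle its nearest subject vertex.

    The subject is first rigidly ICP-aligned to the mean shape (the mean
    surface when available, otherwise the particle cloud), then each
    particle takes the nearest vertex of the aligned subject, ties broken by
    lowest vertex index. Returns ``(indices, residual_distances,
    transform)``.
    """
    mean_particles = np.asarray(mean_particles, dtype=np.float64)
    icp_kwargs = dict(icp_kwargs or {})
    if mean_surface is not None:
        res = alignment.icp_align(subject_mesh, mean_surface, **icp_kwargs)
        transform = res.transform
    else:
        transform = _icp_to_points(subject_mesh.vertices, mean_particles,
                                   **icp_kwargs)
    moved = transform.apply(subject_mesh.vertices)
    tree = cKDTree(moved)
    dist, idx = tree.query(mean_particles, k=4)
    dist, idx = np.atleast_2d(dist), np.atleast_2d(idx)
    # among near-equal distances keep the lowest vertex index
    best = np.empty(len(mean_particles), dtype=np.int64)
    resid = np.empty(len(mean_particles))
    for i in range(len(mean_particles)):
        dmin = dist[i, 0]
        tied = idx[i, dist[i] <= dmin + 1e-12]
        best[i] = tied.min()
        resid[i] = dmin
    return best, resid, transform


def _icp_to_points(source_points, target_points, max_iterations: int = 50,
                   rms_tolerance: float = 1e-6, sample_count: int = 500,
                   seed: int = 0):
    """Rigid ICP of a point set onto a target point cloud (nearest point)."""
    from .geometry import RigidTransform

    rng = np.random.default_rng(seed)
    pts = np.asarray(source_points, dtype=np.float64)
    if len(pts) > sample_count:
        sel = rng.choice(len(pts), size=sample_count, replace=False)
        sel.sort()
        pts = pts[sel]
    tree = cKDTree(np.asarray(target_points, dtype=np.float64))
    transform = RigidTransform.identity()
    moved = pts
    d, j = tree.query(moved)
    rms = float(np.sqrt((d ** 2).mean()))
    for _ in range(max_iterations):
        step = alignment.best_fit_rigid(moved, np.asarray(target_points)[j])
        cand = step.compose(transform)
        moved_new = cand.apply(pts)
        d, j = tree.query(moved_new)
        rms_new = float(np.sqrt((d ** 2).mean()))
        if rms_new > rms + 1e-12:
            break
        improved = rms - rms_new
        transform, moved, rms = cand, moved_new, rms_new
        if improved < rms_tolerance:
            break
    return transform
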