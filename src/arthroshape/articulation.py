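"""Joint-level articular analyses: coverage, joint space, congruence.

The workflow on a pair of mated bone surfaces in their weightbearing frame:

1. seed a *candidate* articular region on each bone by thresholding the
   second principal curvature (K_min),
2. restrict to *covered* vertices — those whose outward surface normal ray
   intersects the opposing candidate region (articular coverage),
3. measure the joint space as closest-point distance at each covered node,
4. evaluate the Ateshian congruence index from the paired mean/Gaussian
   curvatures of the two surfaces, and
5. aggregate per-correspondence-particle statistics across the population,
   plus paired-area t statistics with effect size and post-hoc power.

The congruence index at a contact point with principal curvature
differences D = K_min − K_max on each surface uses the small-angle
approximation cos 2α ≈ 1 (the paired points are selected perpendicularly),
so Δ = |D¹ + D²|, the relative principal curvatures are
K_min/max^e = H¹ + H² ∓ Δ/2, and CI = √((K_min^e² + K_max^e²)/2). CI is 0
exactly for conforming locally spherical (umbilic) contact. Note that
under this printed approximation a pair of perfectly mated *cylinders*
(radius r) yields CI = 1/r, not 0: without the α term the tangential
alignment of the principal directions is invisible. This behaviour is kept
literally and documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from ._proximity import SurfaceProximity, ray_triangle_hits
from .curvature import CurvatureField, principal_from_HG
from .geometry import SurfaceMesh

JOINT_LABELS = ("tibiotalar", "tibiofibular", "talofibular", "synthetic")
COHEN_THRESHOLDS = {"small": 0.2, "medium": 0.5, "large": 0.8}


@dataclass
class ArticularRegion:
    """Vertex/face subset of one bone at the candidate or covered stage."""

    mesh: SurfaceMesh
    vertex_ids: np.ndarray
    face_ids: np.ndarray
    stage: str = "candidate"
    joint_label: str = "synthetic"

    def __post_init__(self):
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=np.int64)
        self.face_ids = np.asarray(self.face_ids, dtype=np.int64)

    @property
    def area(self) -> float:
        """Surface area (mm²): sum of member face areas."""
        return float(self.mesh.face_areas()[self.face_ids].sum())

    @property
    def vertex_mask(self) -> np.ndarray:
        mask = np.zeros(self.mesh.n_vertices, dtype=bool)
        mask[self.vertex_ids] = True
        return mask

    def validate(self) -> None:
        if len(self.vertex_ids) and self.vertex_ids.max() >= self.mesh.n_vertices:
            raise ValueError("vertex id out of range")
        if len(self.face_ids) and self.face_ids.max() >= self.mesh.n_faces:
            raise ValueError("face id out of range")
        mask = self.vertex_mask
        if len(self.face_ids) and not mask[
                self.mesh.faces[self.face_ids]].all():
            raise ValueError("region face with vertex outside region")


def _faces_within(mesh: SurfaceMesh, vertex_mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(vertex_mask[mesh.faces].all(axis=1))


@dataclass
class ThresholdSpec:
    """Selection rule on the second principal curvature.

    ``mode`` 'absolute' compares K_min against ``value`` with ``comparison``
    'below' (concave targets) or 'above'; 'percentile' uses the given
    percentile of K_min over non-boundary vertices as the cut.
    """

    value: float
    comparison: str = "below"
    mode: str = "absolute"
    dilate_rings: int = 0

    def select(self, kmin: np.ndarray, eligible: np.ndarray) -> np.ndarray:
        cut = self.value
        if self.mode == "percentile":
            cut = float(np.percentile(kmin[eligible], self.value))
        elif self.mode != "absolute":
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.comparison == "below":
            sel = kmin < cut
        elif self.comparison == "above":
            sel = kmin > cut
        else:
            raise ValueError(f"unknown comparison {self.comparison!r}")
        return sel & eligible


def candidate_region(mesh: SurfaceMesh, curv: CurvatureField,
                     threshold_spec: ThresholdSpec,
                     joint_label: str = "synthetic",
                     include_boundary: bool = False) -> ArticularRegion:
    """Seed a candidate articular region by thresholding K_min.

    Selected vertices are restricted to the largest connected component of
    the selection on the mesh graph, then optionally dilated by whole
    neighbour rings. Boundary vertices are excluded from seeding by default
    (their curvature estimates are unreliable) but can re-enter through
    dilation.
    """
    eligible = np.ones(mesh.n_vertices, dtype=bool)
    if not include_boundary:
        eligible &= ~curv.boundary
    selected = threshold_spec.select(curv.kmin, eligible)
    if not selected.any():
        raise ValueError(
            f"empty articular selection for threshold {threshold_spec}")

    selected = _largest_component(mesh, selected)
    for _ in range(threshold_spec.dilate_rings):
        touched = np.zeros(mesh.n_vertices, dtype=bool)
        face_hit = selected[mesh.faces].any(axis=1)
        touched[mesh.faces[face_hit].ravel()] = True
        selected |= touched

    vertex_ids = np.flatnonzero(selected)
    region = ArticularRegion(mesh, vertex_ids, _faces_within(mesh, selected),
                             stage="candidate", joint_label=joint_label)
    region.validate()
    return region


def _largest_component(mesh: SurfaceMesh, selected: np.ndarray) -> np.ndarray:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.flatnonzero(selected)
    if len(idx) == 0:
        return selected
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                       mesh.faces[:, [2, 0]]])
    keep = selected[edges].all(axis=1)
    e = remap[edges[keep]]
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                     shape=(len(idx), len(idx)))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        keep_label = int(np.argmax(counts))
        out = np.zeros_like(selected)
        out[idx[labels == keep_label]] = True
        return out
    return selected


def coverage(region_a: ArticularRegion, region_b: ArticularRegion,
             max_ray_length: float = 10.0):
    """Articular coverage: mutual normal-ray intersection of mated regions.

    A vertex of region A is covered iff the ray from it along its outward
    vertex normal intersects a face of region B within ``max_ray_length``
    (and symmetrically for B). Covered faces are faces whose three vertices
    are all covered. Returns ``(covered_a, covered_b)``.
    """
    if region_a.mesh is region_b.mesh:
        raise ValueError("coverage requires regions on distinct meshes")
    out = []
    for src, dst in ((region_a, region_b), (region_b, region_a)):
        normals = src.mesh.vertex_normals()[src.vertex_ids]
        origins = src.mesh.vertices[src.vertex_ids]
        tri = dst.mesh.vertices[dst.mesh.faces[dst.face_ids]]
        hit, _, _ = ray_triangle_hits(origins, normals, tri,
                                      max_length=max_ray_length)
        mask = np.zeros(src.mesh.n_vertices, dtype=bool)
        mask[src.vertex_ids[hit]] = True
        region = ArticularRegion(src.mesh, np.flatnonzero(mask),
                                 _faces_within(src.mesh, mask),
                                 stage="covered", joint_label=src.joint_label)
        region.validate()
        out.append(region)
    return tuple(out)


def joint_space(covered_a: ArticularRegion, mesh_b: SurfaceMesh) -> np.ndarray:
    """Joint-space distance at every covered node of A (mm).

    Unsigned point-to-triangle closest distance from each covered vertex to
    the opposing surface; ordered like ``covered_a.vertex_ids``.
    """
    if len(covered_a.vertex_ids) == 0:
        raise ValueError("empty covered region")
    prox = SurfaceProximity(mesh_b.vertices, mesh_b.faces)
    dist, _, _ = prox.query(covered_a.mesh.vertices[covered_a.vertex_ids])
    return dist


@dataclass
class CongruencePointRecord:
    """Congruence-index ingredients at one paired contact point."""

    D1: float
    D2: float
    delta: float
    alpha: float
    Ke_min: float
    Ke_max: float
    CI: float


def congruence_arrays(Ha, Ga, Hb, Gb):
    """Vectorized congruence index from paired mean/Gaussian curvatures.

    Returns ``(D1, D2, delta, Ke_min, Ke_max, CI)``. Principal curvatures
    come from the H/G quadratic; Δ uses the small-angle approximation
    cos 2α = 1, i.e. Δ = |D1 + D2|.
    """
    Ha, Ga = np.asarray(Ha, float), np.asarray(Ga, float)
    Hb, Gb = np.asarray(Hb, float), np.asarray(Gb, float)
    kmin_a, kmax_a, _ = principal_from_HG(Ha, Ga)
    kmin_b, kmax_b, _ = principal_from_HG(Hb, Gb)
    d1 = kmin_a - kmax_a
    d2 = kmin_b - kmax_b
    delta = np.abs(d1 + d2)  # √(D1² + D2² + 2·D1·D2) with cos2α = 1
    ke_min = Ha + Hb - delta / 2.0
    ke_max = Ha + Hb + delta / 2.0
    ci = np.sqrt((ke_min ** 2 + ke_max ** 2) / 2.0)
    return d1, d2, delta, ke_min, ke_max, ci


def congruence(curv_a: CurvatureField, curv_b: CurvatureField,
               paired_points) -> list[CongruencePointRecord]:
    """Congruence records for index pairs ``(idx_a, idx_b)`` into the fields."""
    pairs = np.asarray(paired_points, dtype=np.int64).reshape(-1, 2)
    ia, ib = pairs[:, 0], pairs[:, 1]
    d1, d2, delta, ke_min, ke_max, ci = congruence_arrays(
        curv_a.H[ia], curv_a.G[ia], curv_b.H[ib], curv_b.G[ib])
    return [CongruencePointRecord(float(d1[i]), float(d2[i]), float(delta[i]),
                                  0.0, float(ke_min[i]), float(ke_max[i]),
                                  float(ci[i]))
            for i in range(len(pairs))]


def pair_opposing_vertices(covered_a: ArticularRegion,
                           covered_b: ArticularRegion) -> np.ndarray:
    """Match each covered vertex of A to the nearest covered vertex of B."""
    pa = covered_a.mesh.vertices[covered_a.vertex_ids]
    pb = covered_b.mesh.vertices[covered_b.vertex_ids]
    tree = cKDTree(pb)
    _, j = tree.query(pa)
    return np.column_stack([covered_a.vertex_ids, covered_b.vertex_ids[j]])


# ---------------------------------------------------------------------------
# population aggregation at correspondence particles

@dataclass
class JointParticleMap:
    """Per-particle, per-subject scalar field with population aggregates."""

    joint_label: str
    particle_ids: np.ndarray
    subject_ids: list
    values: np.ndarray  # (n_subjects, n_included) with NaN where unavailable
    per_particle_mean: np.ndarray = field(init=False)
    per_particle_sd: np.ndarray = field(init=False)

    def __post_init__(self):
        self.particle_ids = np.asarray(self.particle_ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.per_particle_mean = np.nanmean(self.values, axis=0)
        with np.errstate(invalid="ignore"):
            self.per_particle_sd = np.array(
                [np.nan if np.isnan(c).sum() >= len(c) - 1
                 else float(np.nanstd(c, ddof=1)) for c in self.values.T])

    @property
    def pooled(self) -> np.ndarray:
        v = self.values.ravel()
        return v[~np.isnan(v)]

    @property
    def global_mean(self) -> float:
        return float(self.pooled.mean())

    @property
    def global_sd(self) -> float:
        return float(self.pooled.std(ddof=1)) if len(self.pooled) > 1 else float("nan")

    @property
    def global_min(self) -> float:
        return float(self.pooled.min())

    @property
    def global_max(self) -> float:
        return float(self.pooled.max())

    def mean_of_particle_means(self) -> float:
        """Alternative pooling: average the per-particle means."""
        return float(np.nanmean(self.per_particle_mean))

    def sd_of_particle_means(self) -> float:
        return float(np.nanstd(self.per_particle_mean, ddof=1))


def particle_map(per_subject_particle_values: dict, joint_label: str = "synthetic",
                 inclusion_rule: float = 0.5) -> JointParticleMap:
    """Aggregate per-particle values across subjects.

    ``per_subject_particle_values`` maps subject_id → length-P array with
    NaN where the particle's mapped node fell outside the covered region. A
    particle is included iff it has a value for at least ``inclusion_rule``
    of subjects.
    """
    subject_ids = list(per_subject_particle_values)
    table = np.stack([np.asarray(per_subject_particle_values[s], float)
                      for s in subject_ids])
    frac = (~np.isnan(table)).mean(axis=0)
    included = np.flatnonzero(frac >= inclusion_rule)
    if len(included) == 0:
        raise ValueError("no particle satisfies the inclusion rule")
    return JointParticleMap(joint_label, included, subject_ids,
                            table[:, included])


def particle_values_from_nodes(assignments: np.ndarray,
                               node_values: np.ndarray) -> np.ndarray:
    """Lift a per-vertex field (NaN outside the covered region) to particles."""
    return np.asarray(node_values, float)[np.asarray(assignments, int)]


# ---------------------------------------------------------------------------
# paired statistics

@dataclass
class PairedAreaStats:
    """Paired t-test of mated articular areas with effect size and power."""

    n: int
    mean_difference: float
    sd_difference: float
    t: float
    df: int
    p_two_tailed: float
    cohens_d: float
    effect_label: str
    posthoc_power: float
    degenerate: bool = False


def _effect_label(d: float) -> str:
    d = abs(d)
    if d >= COHEN_THRESHOLDS["large"]:
        return "large"
    if d >= COHEN_THRESHOLDS["medium"]:
        return "medium"
    return "small"


def paired_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Post-hoc power of a two-tailed paired t-test (noncentral t)."""
    df = n - 1
    nc = abs(d) * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = float(1 - stats.nct.cdf(tcrit, df, nc)
                  + stats.nct.cdf(-tcrit, df, nc))
    if np.isnan(power):  # extreme noncentrality overflows the nct CDF
        power = float(stats.norm.cdf(nc - tcrit) + stats.norm.cdf(-nc - tcrit))
    return power


def paired_area_stats(areas_a, areas_b, alpha: float = 0.05) -> PairedAreaStats:
    """Compare mated articular surface areas with a paired t-test.

    Cohen's d is the mean paired difference over its SD; the post-hoc power
    uses the noncentral t distribution with noncentrality d·√n at the given
    two-tailed α. A zero-SD difference vector is flagged degenerate rather
    than asserted significant.
    """
    a = np.asarray(areas_a, dtype=np.float64)
    b = np.asarray(areas_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    df = n - 1
    if sd_d == 0:
        return PairedAreaStats(n, mean_d, 0.0, float("nan"), df, float("nan"),
                               float("nan"), "small" if mean_d == 0 else "large",
                               float("nan"), degenerate=True)
    t = mean_d / (sd_d / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df))
    d = mean_d / sd_d
    return PairedAreaStats(n, mean_d, sd_d, float(t), df, p, float(d),
                           _effect_label(d), paired_t_power(d, n, alpha))


def required_n(d: float, alpha: float = 0.05, power: float = 0.8,
               n_max: int = 10_000_000) -> int:
    """Smallest paired-sample n reaching the target two-tailed power.

    Searches the noncentral-t power function, starting from the normal
    approximation n ≈ ((z_{1−α/2} + z_power)/d)².
    """
    if not (d > 0 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("require d > 0, 0 < alpha < 1, 0 < power < 1")
    z = stats.norm.ppf
    guess = int(((z(1 - alpha / 2) + z(power)) / d) ** 2)
    n = max(2, guess - 5)
    while n <= n_max and paired_t_power(d, n, alpha) < power:
        n += 1
    if n > n_max:
        raise ValueError("required sample size exceeds search bound")
    # back off in case the guess overshot the true minimum
    while n > 2 and paired_t_power(d, n - 1, alpha) >= power:
        n -= 1
    return n
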