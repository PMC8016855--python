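"""Synthetic mated joints and shape populations with analytic ground truth.

Every stage of the joint pipeline can be validated without CT data: the
joint generator builds pairs of mated open articular patches (ball-and-
socket, mated cylinders, saddle-on-groove trochlea, parallel planes) whose
mean/Gaussian curvature and gap field are known in closed form, and the
population generator builds cohorts of bone-like meshes as a template plus
k orthogonal latent shape modes with stated SDs, vertex noise, random
similarity pose and optional left-side mirroring — the ground-truth record
keeps the planted coefficients so mode recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .geometry import SurfaceMesh, reflect_mesh

FAMILIES = ("sphere_socket", "cylinder_pair", "trochlea_pair", "plane_pair")


@dataclass
class SyntheticJointSpec:
    """Parameters of a mated articular patch pair.

    ``radius_a`` is the convex member, ``radius_b`` the concave one (for
    ``sphere_socket`` consistency requires radius_b = radius_a + gap when
    the centers coincide); ``angular_extent`` is the patch half-angle in
    degrees (patch half-width in mm for plane/trochlea families);
    ``resolution`` is the target edge length in mm.
    """

    family: str = "sphere_socket"
    radius_a: float = 10.0
    radius_b: float = 12.0
    gap: float = 2.0
    angular_extent: float = 80.0
    resolution: float = 1.0
    center_offset: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.center_offset = np.asarray(self.center_offset, dtype=np.float64)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown joint family {self.family!r}")
        if self.radius_a <= 0 or self.radius_b <= 0:
            raise ValueError("radii must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")


@dataclass
class JointOracle:
    """Exact per-vertex curvature and gap fields for a generated joint."""

    spec: SyntheticJointSpec
    H_a: np.ndarray
    G_a: np.ndarray
    H_b: np.ndarray
    G_b: np.ndarray
    gap_a: np.ndarray  # exact closest-gap at each vertex of mesh A


def _grid_faces(nu: int, nv: int, flip: bool = False) -> np.ndarray:
    """Triangulate an (nu × nv) structured grid of vertex indices."""
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1),
                            np.stack([a, c, d], axis=1)])
    return faces[:, ::-1] if flip else faces


def _spherical_patch(radius: float, extent_deg: float, resolution: float,
                     center, concave: bool):
    """Open spherical cap around +z; winding gives outward (+radial) normals
    for the convex member and inward (−radial, toward the joint space)
    normals for the concave member."""
    extent = np.radians(extent_deg)
    n_theta = max(3, int(np.ceil(radius * extent / resolution)) + 1)
    n_phi = max(8, int(np.ceil(2 * np.pi * radius * np.sin(extent) / resolution)))
    theta = np.linspace(extent / n_theta, extent, n_theta)
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    pts = radius * np.stack([np.sin(tt) * np.cos(pp),
                             np.sin(tt) * np.sin(pp),
                             np.cos(tt)], axis=-1).reshape(-1, 3)
    # rings with azimuthal wraparound plus an apex fan
    apex = np.array([[0.0, 0.0, radius]])
    vertices = np.vstack([apex, pts])
    idx = 1 + np.arange(n_theta * n_phi).reshape(n_theta, n_phi)
    faces = []
    for j in range(n_phi):
        faces.append((0, idx[0, j], idx[0, (j + 1) % n_phi]))
    for i in range(n_theta - 1):
        for j in range(n_phi):
            j2 = (j + 1) % n_phi
            faces.append((idx[i, j], idx[i + 1, j], idx[i + 1, j2]))
            faces.append((idx[i, j], idx[i + 1, j2], idx[i, j2]))
    faces = np.array(faces, dtype=np.int64)
    if concave:
        faces = faces[:, ::-1]
    return vertices + np.asarray(center), faces


def make_joint(spec: SyntheticJointSpec):
    """Generate two mated open patches plus their analytic oracle.

    Mesh A is the convex member (bone-outward normals, positive curvature),
    mesh B the concave one (negative curvature with respect to its own
    outward normals, which point into the joint space).
    """
    rng = np.random.default_rng(spec.seed)
    ra, rb, g = spec.radius_a, spec.radius_b, spec.gap
    off = spec.center_offset

    if spec.family == "sphere_socket":
        va, fa = _spherical_patch(ra, spec.angular_extent, spec.resolution,
                                  np.zeros(3), concave=False)
        vb, fb = _spherical_patch(rb, spec.angular_extent, spec.resolution,
                                  off, concave=True)
        Ha = np.full(len(va), 1.0 / ra)
        Ga = np.full(len(va), 1.0 / ra ** 2)
        Hb = np.full(len(vb), -1.0 / rb)
        Gb = np.full(len(vb), 1.0 / rb ** 2)
        gap_a = rb - np.linalg.norm(va - off, axis=1)
    elif spec.family == "plane_pair":
        half = spec.radius_a  # half-width in mm for planar patches
        n = max(2, int(np.ceil(2 * half / spec.resolution)) + 1)
        x = np.linspace(-half, half, n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        va = np.stack([xx, yy, np.zeros_like(xx)], axis=-1).reshape(-1, 3)
        fa = _grid_faces(n, n)  # normals +z (outward of the lower bone)
        vb = va.copy() + np.array([0.0, 0.0, g]) + off
        fb = _grid_faces(n, n, flip=True)  # normals −z, toward the gap
        Ha = Ga = np.zeros(len(va))
        Hb = Gb = np.zeros(len(vb))
        gap_a = np.full(len(va), float(g + off[2]))
    elif spec.family == "cylinder_pair":
        # convex half-cylinder (axis y) under a concave trough
        extent = np.radians(spec.angular_extent)
        n_arc = max(4, int(np.ceil(2 * extent * ra / spec.resolution)) + 1)
        length = 2 * ra
        n_len = max(2, int(np.ceil(length / spec.resolution)) + 1)
        ang = np.linspace(-extent, extent, n_arc)
        y = np.linspace(-length / 2, length / 2, n_len)
        aa, yy = np.meshgrid(ang, y, indexing="ij")
        va = np.stack([ra * np.sin(aa), yy, ra * np.cos(aa)],
                      axis=-1).reshape(-1, 3)
        fa = _grid_faces(n_arc, n_len)  # outward (+radial) normals
        vb = np.stack([rb * np.sin(aa), yy, rb * np.cos(aa)],
                      axis=-1).reshape(-1, 3) + off
        fb = _grid_faces(n_arc, n_len, flip=True)  # normals toward the gap
        Ha = np.full(len(va), 1.0 / (2 * ra))
        Ga = np.zeros(len(va))
        Hb = np.full(len(vb), -1.0 / (2 * rb))
        Gb = np.zeros(len(vb))
        radial = np.linalg.norm((va - off)[:, [0, 2]], axis=1)
        gap_a = rb - radial
    elif spec.family == "trochlea_pair":
        # saddle graph z = x²/(2 ra) − y²/(2 rb) and its mated groove
        half = min(ra, rb) * 0.4
        n = max(3, int(np.ceil(2 * half / spec.resolution)) + 1)
        x = np.linspace(-half, half, n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        za = xx ** 2 / (2 * ra) - yy ** 2 / (2 * rb)
        va = np.stack([xx, yy, za], axis=-1).reshape(-1, 3)
        fa = _grid_faces(n, n)  # upward normals: outward of the bone below
        vb = np.stack([xx, yy, za + g], axis=-1).reshape(-1, 3) + off
        fb = _grid_faces(n, n, flip=True)
        Ha, Ga = _graph_saddle_curvature(xx.ravel(), yy.ravel(), ra, rb,
                                         outward_up=True)
        Hb, Gb = _graph_saddle_curvature(xx.ravel(), yy.ravel(), ra, rb,
                                         outward_up=False)
        gap_a = np.full(len(va), float(g))  # vertical gap; exact at the crest
    else:  # pragma: no cover - guarded by the spec validator
        raise ValueError(spec.family)

    if spec.noise_sd > 0:
        va = va + rng.normal(0, spec.noise_sd, va.shape)
        vb = vb + rng.normal(0, spec.noise_sd, vb.shape)

    mesh_a = SurfaceMesh(va, fa, bone_label="synthetic", subject_id="convex")
    mesh_b = SurfaceMesh(vb, fb, bone_label="synthetic", subject_id="concave")
    mesh_a.validate()
    mesh_b.validate()
    oracle = JointOracle(spec, Ha, Ga, Hb, Gb, gap_a)
    return mesh_a, mesh_b, oracle


def _graph_saddle_curvature(x, y, r1, r2, outward_up: bool):
    """Exact H, G of z = x²/(2 r1) − y²/(2 r2) with chosen normal side."""
    fx = x / r1
    fy = -y / r2
    fxx = 1.0 / r1
    fyy = -1.0 / r2
    fxy = 0.0
    w = 1.0 + fx ** 2 + fy ** 2
    H = ((1 + fy ** 2) * fxx - 2 * fx * fy * fxy + (1 + fx ** 2) * fyy) \
        / (2 * w ** 1.5)
    G = (fxx * fyy - fxy ** 2) / w ** 2
    if not outward_up:
        H = -H
    return np.asarray(H) + 0 * x, np.asarray(G) + 0 * x


def analytic_curvature(spec: SyntheticJointSpec, points: np.ndarray,
                       side: str = "a", tolerance: float = 1e-6):
    """Closed-form (H, G) at surface points with bone-outward signs.

    ``side`` 'a' is the convex member, 'b' the concave one. Points must lie
    on the parametric surface within ``tolerance``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if spec.family == "sphere_socket":
        r = spec.radius_a if side == "a" else spec.radius_b
        center = np.zeros(3) if side == "a" else spec.center_offset
        err = np.abs(np.linalg.norm(pts - center, axis=1) - r)
        sign = 1.0 if side == "a" else -1.0
        H = np.full(len(pts), sign / r)
        G = np.full(len(pts), 1.0 / r ** 2)
    elif spec.family == "plane_pair":
        z0 = 0.0 if side == "a" else spec.gap + spec.center_offset[2]
        err = np.abs(pts[:, 2] - z0)
        H = np.zeros(len(pts))
        G = np.zeros(len(pts))
    elif spec.family == "cylinder_pair":
        r = spec.radius_a if side == "a" else spec.radius_b
        center = np.zeros(3) if side == "a" else spec.center_offset
        err = np.abs(np.linalg.norm((pts - center)[:, [0, 2]], axis=1) - r)
        sign = 1.0 if side == "a" else -1.0
        H = np.full(len(pts), sign / (2 * r))
        G = np.zeros(len(pts))
    elif spec.family == "trochlea_pair":
        base = pts - (0 if side == "a"
                      else np.append(spec.center_offset[:2], 0))
        z0 = base[:, 0] ** 2 / (2 * spec.radius_a) \
            - base[:, 1] ** 2 / (2 * spec.radius_b)
        if side == "b":
            z0 = z0 + spec.gap + spec.center_offset[2]
        err = np.abs(pts[:, 2] - z0)
        H, G = _graph_saddle_curvature(base[:, 0], base[:, 1], spec.radius_a,
                                       spec.radius_b, outward_up=(side == "a"))
    else:  # pragma: no cover
        raise ValueError(spec.family)
    if err.max(initial=0.0) > tolerance:
        raise ValueError(
            f"point {int(np.argmax(err))} is {err.max():.2e} mm off-surface")
    return H, G


def make_joint_cohort(n_subjects: int = 10,
                      base: SyntheticJointSpec | None = None,
                      radius_sd: float = 0.5,
                      rotation_range_deg: float = 15.0,
                      translation_range_mm: float = 10.0,
                      seed: int = 0):
    """Cohort of mated joints with per-subject size and pose variation.

    Each subject gets its own convex radius (base ± N(0, radius_sd²)) with
    the concave radius tracking it so the gap stays at the base value, and
    a random rigid pose applied to *both* members (the joint space is pose
    invariant). Returns ``(cohort, oracles)`` where cohort maps subject_id
    → {"ball": mesh, "socket": mesh}.
    """
    base = base or SyntheticJointSpec()
    rng = np.random.default_rng(seed)
    cohort, oracles = {}, {}
    for i in range(n_subjects):
        ra = max(base.radius_a + rng.normal(0, radius_sd), base.radius_a / 2)
        spec = SyntheticJointSpec(
            family=base.family, radius_a=ra, radius_b=ra + base.gap,
            gap=base.gap, angular_extent=base.angular_extent,
            resolution=base.resolution, noise_sd=base.noise_sd,
            seed=int(rng.integers(2 ** 31)))
        a, b, oracle = make_joint(spec)
        rot = _random_rotation(rng, rotation_range_deg)
        trans = rng.uniform(-translation_range_mm, translation_range_mm, 3)
        for m in (a, b):
            m.vertices = m.vertices @ rot.T + trans
            m.subject_id = f"S{i:03d}"
        cohort[f"S{i:03d}"] = {"ball": a, "socket": b}
        oracles[f"S{i:03d}"] = oracle
    return cohort, oracles


# ---------------------------------------------------------------------------
# populations

@dataclass
class PopulationSpec:
    """Cohort of bone-like meshes: template + k latent modes + pose/noise."""

    template: SurfaceMesh
    n_subjects: int = 20
    k_modes: int = 2
    mode_sds: np.ndarray = dc_field(default_factory=lambda: np.array([3.0, 2.0]))
    mode_fields: np.ndarray | None = None  # (k, n_vertices, 3), orthonormal
    vertex_noise_sd: float = 0.05
    rotation_range_deg: float = 20.0
    translation_range_mm: float = 10.0
    scale_range: tuple = (1.0, 1.0)
    left_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.mode_sds = np.asarray(self.mode_sds, dtype=np.float64)
        if len(self.mode_sds) != self.k_modes:
            raise ValueError("mode_sds length must equal k_modes")
        if (np.diff(self.mode_sds) > 0).any():
            raise ValueError("mode_sds must be descending")


@dataclass
class PopulationTruth:
    """Planted coefficients and poses of a generated cohort."""

    mode_fields: np.ndarray
    coefficients: np.ndarray  # (n_subjects, k)
    rotations: np.ndarray
    translations: np.ndarray
    scales: np.ndarray
    sides: list


def smooth_mode_fields(vertices: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k orthonormal smooth low-frequency displacement fields.

    Deterministic from the seed: random low-frequency sinusoids of linear
    coordinate forms on each axis, Gram–Schmidt orthonormalized as
    3n-vectors (unit norm, mutually orthogonal within 1e-12).
    """
    rng = np.random.default_rng(seed)
    n = len(vertices)
    span = max(np.ptp(vertices, axis=0).max(), 1e-9)
    fields = []
    raw = []
    while len(raw) < k:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        freq = rng.uniform(0.5, 2.0) * np.pi / span
        phase = rng.uniform(0, 2 * np.pi)
        profile = np.sin(freq * (vertices @ rng.normal(size=3)) + phase)
        raw.append(np.outer(profile, direction).ravel())
    for vec in raw:
        for prev in fields:
            vec = vec - (vec @ prev) * prev
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            continue
        fields.append(vec / norm)
    while len(fields) < k:  # extremely unlikely; top up with fresh draws
        extra = smooth_mode_fields(vertices, k - len(fields),
                                   seed=seed + 1000 + len(fields))
        for f2 in extra.reshape(len(extra), -1):
            vec = f2
            for prev in fields:
                vec = vec - (vec @ prev) * prev
            norm = np.linalg.norm(vec)
            if norm >= 1e-9:
                fields.append(vec / norm)
    return np.stack(fields[:k]).reshape(k, n, 3)


def _random_rotation(rng, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_deg, max_deg))
    kmat = np.array([[0, -axis[2], axis[1]],
                     [axis[2], 0, -axis[0]],
                     [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * kmat + (1 - np.cos(ang)) * kmat @ kmat


def make_population(popspec: PopulationSpec):
    """Generate a cohort: template + planted modes + noise + random pose.

    Subject i is template + Σ_k b_ik·mode_field_k with b_ik ~ N(0, sd_k²),
    plus isotropic vertex noise, then a random similarity pose; the first
    ⌊left_fraction·n⌋ subjects are mirrored and labeled left. Returns
    ``(meshes, truth)`` with all planted quantities recorded.
    """
    rng = np.random.default_rng(popspec.seed)
    template = popspec.template
    n = popspec.n_subjects
    k = popspec.k_modes
    if popspec.mode_fields is not None:
        fields = np.asarray(popspec.mode_fields, dtype=np.float64)
    elif k > 0:
        fields = smooth_mode_fields(template.vertices, k, seed=popspec.seed)
    else:
        fields = np.zeros((0, template.n_vertices, 3))
    flat = fields.reshape(k, 3 * template.n_vertices)
    if k > 1:
        gram = flat @ flat.T
        if not np.allclose(gram, np.eye(k), atol=1e-6):
            raise ValueError("mode_fields not orthonormal")

    coeffs = rng.normal(size=(n, k)) * popspec.mode_sds[None, :] if k else \
        np.zeros((n, 0))
    n_left = int(np.floor(popspec.left_fraction * n))
    meshes = []
    rotations = np.empty((n, 3, 3))
    translations = np.empty((n, 3))
    scales = np.empty(n)
    sides = []
    for i in range(n):
        v = template.vertices.copy()
        for j in range(k):
            v = v + coeffs[i, j] * fields[j]
        if popspec.vertex_noise_sd > 0:
            v = v + rng.normal(0, popspec.vertex_noise_sd, v.shape)
        rot = _random_rotation(rng, popspec.rotation_range_deg)
        trans = rng.uniform(-popspec.translation_range_mm,
                            popspec.translation_range_mm, 3)
        scale = rng.uniform(*popspec.scale_range)
        v = scale * (v @ rot.T) + trans
        mesh = SurfaceMesh(v, template.faces.copy(), bone_label=template.bone_label,
                           side="right", subject_id=f"S{i:03d}")
        if i < n_left:
            mesh = reflect_mesh(mesh)  # stored as a left specimen
            mesh.side = "left"
        meshes.append(mesh)
        rotations[i] = rot
        translations[i] = trans
        scales[i] = scale
        sides.append(mesh.side)
    truth = PopulationTruth(fields, coeffs, rotations, translations, scales,
                            sides)
    return meshes, truth
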