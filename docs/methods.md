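# Methods

This note documents the models, estimators, numerical choices, and
limitations behind `arthroshape`. Units are millimetres (lengths), mm²
(areas), mm⁻¹ (curvature, congruence index), mm⁻² (Gaussian curvature)
throughout; no unit inference is performed.

## Surface preprocessing

Input surfaces are triangulated PLY meshes (ascii 1.0 or
binary_little_endian 1.0) in the scanner frame. Stored normals are never
trusted; orientation always derives from face winding (counter-clockwise
from outside). Left bones are mirrored across the scanner's YZ plane
(x → −x, configurable axis) with face winding reversed so outward
orientation survives; the side label flips.

Smoothing is Taubin's two-step λ/μ scheme (λ = 0.5, μ = −0.53, 10
iterations by default) — volume-preserving, unlike plain Laplacian
smoothing, which matters because articular curvature is the downstream
signal. Decimation is quadric edge collapse (Garland–Heckbert) with
normal-flip rejection; on a fine sphere, halving the face count changes
area by < 0.1%. Cutting planes clip exactly: crossing faces are split at
edge–plane intersections and the boundary is left open (cropped shaft
bones are not capped).

## Alignment

- `best_fit_rigid` is the Kabsch/Umeyama SVD solution with det(R) = +1
  enforced; reflections are never produced by any fit.
- ICP is point-to-surface: seeded uniform vertex subsample (default 500),
  exact closest-point correspondences, and per iteration both a
  point-to-point SVD step and a linearized point-to-plane step are tried,
  keeping whichever lowers the point-to-surface RMS — this keeps the
  objective monotone (asserted) while converging in a handful of
  iterations. Non-convergence returns the best pose found, flagged.
- Cross-subject alignment registers each subject's *reference bone*
  (talus) to the reference subject's and applies that transform to the
  whole bone set, preserving the within-subject weightbearing pose.
- GPA: configurations are centred and (optionally) normalized to unit
  centroid size (root-sum-of-squares about the centroid — the size metric
  chosen here), then rotated batchwise onto the evolving mean until the
  mean stops moving (tol 1e-10). Batch updates plus an order-invariant
  initial mean make the result independent of subject ordering.
- The common cutting plane sits, along the shaft axis (+z of the aligned
  frame by default), at the minimum over subjects of each subject's
  maximal extent — the most proximal level present in every specimen —
  with the normal pointing proximal (clipping discards the shaft).

## Correspondence model

Entropy-optimized particle systems (the ShapeWorks family) solve
correspondence with a population objective. The scheme here is a
deliberately simpler, fully deterministic template propagation:

1. template = the subject with minimal summed light-ICP RMS to all others
   (medoid; ties broken by subject id);
2. P particles farthest-point sampled on the template surface (P = 1024
   default; seeded start vertex; restricted distal to the cutting plane
   when one is supplied);
3. propagation: ICP template→subject, then exact closest-point projection
   of each particle onto the subject surface;
4. optional refinement rounds re-project the evolving cross-subject mean
   onto every subject (1 round by default).

Every particle therefore lies exactly on its subject's surface (a 0.5 mm
tolerance is still enforced as an invariant). Consequence of the
simplification: correspondence quality depends on the template-to-subject
projection being well-behaved, so mode variance fractions on real
populations should be treated as approximate relative to entropy-optimized
models. Mode *recovery* on synthetic populations with planted orthogonal
modes is exact to within sampling error, which is what the tests assert.

GPA for the model removes pose and size; the aligned sets and their mean
are then rescaled by the cohort-mean original centroid size. This keeps
all downstream quantities (eigenvalue mm², warp displacements, distance
maps) in millimetres while leaving size variation out of the shape space —
without it, "±2 SD" would live on a unit-size shape manifold with no
physical scale.

The mean surface warps the template mesh by a 3D biharmonic (kernel r)
thin-plate spline on the template-particle → mean-particle displacements,
with zero smoothing: particle displacements are reproduced exactly at
particle sites. Mode warps displace the mean particles by k·√λ·v (λ the
covariance eigenvalue, v the unit eigenvector — "k SD" means k·√λ) and TPS
the mean surface the same way.

## PCA and parallel analysis

PCA runs on raw mean-centred particle coordinates (all coordinates share
units; no column standardization), covariance with the n−1 denominator,
diagonalized by SVD (rank-revealing: at most n−1 nonzero eigenvalues,
clamped at 0). Variance fractions are eigenvalue shares of the total.

Mode retention is Horn's parallel analysis at the 95th percentile: the
observed matrix is column-standardized and its correlation-matrix
eigenvalues are compared index-by-index against eigenvalues of 200
standard-normal matrices of the same shape, standardized identically.
Retention stops at the first failure. Two deliberate choices: the null is
standardized like the data (classic Horn/Glorfeld), and the percentile
uses the conservative 'higher' order statistic. Note the test is exact at
its nominal level: on pure noise the first eigenvalue beats the 95th
percentile about 5% of the time by construction, so "retains 0 modes" is
expected in ~95% of null runs, not all of them.

## Curvature

Per-vertex mean curvature comes from the cotangent mean-curvature normal
with mixed Voronoi areas (Meyer et al., obtuse-safe), signed by projection
onto the area-weighted outward vertex normal: convex bone regions give
H > 0 (sphere of radius r: H = +1/r; socket: −1/r). Gaussian curvature is
the angle defect over the same area — summed over a closed mesh this is
exactly 2πχ, which the tests assert to 1e-9 (Gauss–Bonnet). Principal
curvatures follow from K² − 2HK + G = 0:

    K_min = H − √(H² − G),  K_max = H + √(H² − G).

Discrete H, G need not satisfy H² ≥ G; the discriminant is clamped at 0
and the vertex flagged. "Second principal curvature" is defined as K_min,
the algebraically smaller value — the natural threshold signal for concave
articular facets. Boundary vertices get values but are flagged unreliable
and excluded from region seeding by default. No attempt is made to match
any particular FE post-processor's estimator; parity with analytic values
on parametric surfaces (sphere, cylinder, plane, saddle) is the
correctness standard, with refinement convergence verified (< 0.7 error
ratio per edge halving).

## Coverage, joint space, congruence

Candidate regions threshold K_min (absolute value or percentile,
sign-aware), keep the largest connected component on the mesh graph, and
optionally dilate by whole neighbour rings. Coverage casts a ray from each
candidate vertex along its outward normal (Möller–Trumbore) against the
opposing candidate faces only, within max_ray_length (default 10 mm — no
anatomical joint space approaches this); a face is covered when all three
vertices are. Enlarging max_ray_length never shrinks coverage (asserted).
Joint space is the unsigned point-to-triangle closest distance from each
covered vertex to the opposing surface — bone-to-bone; cartilage is
invisible to weightbearing CT and out of scope.

Congruence pairs each covered vertex of the first surface with the
nearest covered vertex of the opposing surface and evaluates, from the
paired (H, G):

    D^s = K^s_min − K^s_max           (≤ 0, each surface)
    Δ   = |D¹ + D²|                   (small-angle form, cos 2α ≡ 1)
    K^e_min/max = H¹ + H² ∓ Δ/2
    CI  = √((K^e_min² + K^e_max²)/2)

The small-angle form is kept literally. Its boundary: Δ ignores the
relative orientation α of the principal directions, so CI = 0 holds
exactly only for locally umbilic contact (sphere-in-socket). Perfectly
mated cylinders of radius r score CI = 1/r under this formula — by
construction, not by defect of the implementation; tests document the
value. CI is symmetric under swapping the surfaces and scales as 1/s when
all lengths scale by s.

## Population aggregation and statistics

Particle-level maps: each subject's covered-node field (distance or CI) is
lifted to correspondence particles via nearest-vertex assignments
(subject ICP-aligned to the mean shape; ties at equal distance take the
lowest vertex index). A particle enters the population map when it has a
value for ≥ 50% of subjects (configurable). Reports give per-particle
mean ± SD and two global poolings — all (subject, particle) values pooled,
and the mean of per-particle means — because summary tables in this
literature do not always state which convention they use; both are
emitted.

Coverage areas are compared by a paired t-test (df = n−1, two-tailed),
Cohen's d = mean difference / SD of differences with the 0.2/0.5/0.8
small/medium/large labels, and post-hoc power from the noncentral t
distribution with noncentrality d·√n at α = 0.05. A zero-SD difference
vector is flagged degenerate, not asserted significant. `required_n`
searches the noncentral-t power function for the smallest n reaching a
target power, seeded by the normal approximation
((z_{1−α/2} + z_power)/d)²; the exact count typically lands 1–3 above the
approximation (the usual df correction).

## Synthetic data: what it emulates, what it does not

The joint generator builds open mated patches — open like clipped bones,
to exercise boundary handling — with exact oracles:

- `sphere_socket`: convex cap radius r_a, concave cap r_b = r_a + gap
  (center offset optional); H = ±1/r, G = 1/r², gap field
  r_b − |p − c| in closed form.
- `cylinder_pair`: H = ±1/(2r), G = 0.
- `trochlea_pair`: saddle graph z = x²/(2r₁) − y²/(2r₂) with the full
  closed-form graph curvatures (H = (1/r₁ − 1/r₂)/2 at the crest).
- `plane_pair`: H = G = 0, constant gap.

Populations are template + k orthonormal smooth low-frequency displacement
fields with Gaussian coefficients (SDs descending), isotropic vertex
noise, random similarity pose, and optional mirrored "left" subjects.
Default condition for mode-recovery experiments: n = 40 subjects, planted
SDs 3/2/1 mm, vertex noise SD 0.05 mm — an SNR regime comparable to
segmented bone surfaces, where anatomical modes are millimetres and
segmentation jitter is a small fraction of a voxel. Recovery is scored
against the *realized* sample variances of the drawn coefficients, which
is the exact oracle for a finite cohort (population SD ratios are only
approached as n → ∞).

What the generator does not emulate: anatomically realistic bone
templates, spatially correlated segmentation error, cartilage, imaging
artifacts, or multi-bone pose covariation. Passing tests therefore
demonstrate correctness of the estimators and pipeline mechanics under
known ground truth — not that any particular anatomical cohort will yield
a given number of significant modes.

## Problem sizes and determinism

Test and demo cohorts use coarse meshes (edge length ~1 mm, a few hundred
to a few thousand vertices per bone) and 96–1024 particles; the pipeline
scales to segmented-bone resolution linearly in vertices × subjects. Every
random choice (sampling, null replicates, synthetic draws) flows from an
explicit integer seed; identical inputs and seed give bit-identical
models, meshes and CSVs (asserted).

## Known limitations

- Template-propagation correspondence can slide along near-symmetric
  surfaces (a sphere has no unique parameterization); anatomical bones
  break the symmetry in practice, synthetic tests use asymmetric shapes
  where identifiability matters.
- Point-to-plane ICP linearization assumes small per-step rotations;
  gross misalignment (> ~30°) may need an initial pose.
- The coverage definition is purely geometric (normal-ray intersection)
  and inherits mesh-resolution granularity at region boundaries.
- Congruence uses nearest-vertex curvature pairing across the joint
  space; strongly oblique pairings would reintroduce the α term that the
  small-angle form discards.
- Single-domain shape models only: per-bone variation, no joint-pose
  modes.
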