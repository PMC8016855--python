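# arthroshape

Correspondence-based statistical shape modeling and joint-level articular
analysis for bone surface meshes — built for talocrural (ankle) morphometry
from weightbearing CT, and usable for any mated articulation.

## What it does

Given per-subject triangulated bone surfaces (tibia, fibula, talus as PLY,
millimetres, posed in the scanner frame), the pipeline quantifies:

1. **Anatomical shape variation.** Bones are mirrored to a common side,
   smoothed/decimated, ICP-aligned across subjects with the talus as the
   reference bone (preserving each subject's weightbearing joint pose), and
   cropped at the most proximal plane common to all specimens. A
   correspondence model places P index-matched surface particles on every
   bone (default P = 1024), generalized Procrustes analysis removes pose and
   size, and PCA of the n×3P particle matrix yields modes of variation.
   Horn's parallel analysis decides how many modes exceed chance, and the
   mean surface is warped ±2 SD along each retained mode with
   surface-distance color maps.

2. **Articular coverage.** On each mated surface pair, a candidate articular
   region is seeded by thresholding the second principal curvature
   K_min = H − √(H² − G) (concave facets have K_min < 0); a vertex is
   *covered* when the ray along its outward normal intersects the opposing
   candidate region. Covered areas are compared with a paired t-test,
   Cohen's d and noncentral-t post-hoc power.

3. **Joint-space distance.** Closest-point (point-to-triangle) distance from
   every covered node to the opposing surface — subchondral bone to bone.

4. **Congruence index** (Ateshian). At paired contact points with mean and
   Gaussian curvatures (H, G) per surface, principal curvatures are
   K_min/max = H ∓ √(H² − G); with curvature differences D = K_min − K_max
   per surface and the small-angle approximation cos 2α ≈ 1,

       Δ = |D¹ + D²|,   K^e_min/max = H¹ + H² ∓ Δ/2,
       CI = √((K^e_min² + K^e_max²)/2)   [mm⁻¹],

   which is 0 for perfectly conforming locally spherical contact.

Per-particle population maps (mean ± SD at every correspondence particle)
and Table-style reports (coverage areas + paired statistics; distance and
CI mean ± SD, min, max) are emitted as CSV.

A synthetic module generates mated joints (ball-and-socket, cylinder pair,
saddle trochlea, parallel planes) with closed-form curvature and gap
oracles, plus shape populations with planted orthogonal modes — every
pipeline stage is testable without CT data.

## Worked example

Simulate a ball-and-socket joint (convex radius 10 mm inside a 12 mm
socket, 2 mm joint space) and analyze it:

```sh
arthroshape simulate --family sphere_socket --radius-a 10 --radius-b 12 \
    --gap 2 --resolution 0.8 --out demo
arthroshape articulate demo/convex.ply demo/concave.ply \
    --threshold-a 0.05 --threshold-b -0.05 --out demo/report.json
```

prints

```json
{
 "covered_area_a_mm2": 473.46009466324347,
 "covered_area_b_mm2": 635.522749886612,
 "distance_mean_mm": 1.9933110081851986,
 "distance_min_mm": 1.9881472144946803,
 "distance_max_mm": 1.9989919357431083,
 "ci_mean_mm-1": 0.016677605078904322,
 "ci_min_mm-1": 0.016651245751088853,
 "ci_max_mm-1": 0.016698636908746747
}
```

The joint space reproduces the constructed 2 mm gap to mesh resolution, and
the congruence index matches the analytic value for this pair: both
surfaces are umbilic, so CI = 1/10 − 1/12 = 1/60 ≈ 0.0167 mm⁻¹. Covered
area differs between members because the socket (r = 12) is intrinsically
larger than the ball (r = 10) over the same solid angle — the same effect
that makes a tibial plafond larger than the talar dome it covers.

The full cohort pipeline is driven by a YAML config
(`arthroshape run config.yaml`) with a manifest of
(subject, side, bone, path) rows; see `arthroshape.pipeline.PipelineConfig`.

## Notes

- The correspondence optimizer is a deliberately simplified
  template-propagation scheme (farthest-point sampling + ICP projection +
  mean re-projection), not an entropy-based particle system; see
  `docs/methods.md` for what this does and does not preserve.
- The congruence chain implements the printed small-angle form literally:
  with cos 2α ≡ 1, perfectly mated *cylinders* score CI = 1/r, not 0.
  `docs/methods.md` discusses this boundary of the approximation.
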