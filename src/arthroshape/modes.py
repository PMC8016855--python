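"""PCA shape modes, parallel-analysis retention, and mode warps.

The GPA-aligned particle arrays of a cohort form an n×3P matrix whose
principal components are the bone's modes of variation. Horn's parallel
analysis decides how many leading modes exceed chance; walking ±k·√λ along
a retained eigenvector and thin-plate-spline-warping the mean surface
visualizes what each mode does anatomically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._tps import tps_warp
from .geometry import SurfaceMesh, surface_to_surface_distance


@dataclass
class ShapeModeSet:
    """PCA decomposition of particle coordinates.

    ``eigenvalues`` are the covariance eigenvalues (mm², descending,
    n−1 denominator); ``eigenvectors[i]`` is the unit-norm length-3P mode
    direction; ``variance_fraction[i] = λ_i / Σλ``. ``n_significant`` is
    filled in by :func:`parallel_analysis` when requested.
    """

    mean_vector: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fraction: np.ndarray
    n_subjects: int
    n_significant: int | None = None

    @property
    def n_particles(self) -> int:
        return len(self.mean_vector) // 3

    def validate(self) -> None:
        ev = self.eigenvalues
        if (np.diff(ev) > 1e-12).any():
            raise ValueError("eigenvalues not sorted descending")
        if (ev < -1e-12).any():
            raise ValueError("negative eigenvalue")
        gram = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(gram, np.eye(len(ev)), atol=1e-9):
            raise ValueError("eigenvectors not orthonormal")
        if self.variance_fraction.sum() > 1 + 1e-12:
            raise ValueError("variance fractions exceed 1")
        if int((ev > 1e-12 * max(ev.max(initial=0.0), 1.0)).sum()) > self.n_subjects - 1:
            raise ValueError("more nonzero modes than n_subjects - 1")

    def scores(self, data_matrix: np.ndarray) -> np.ndarray:
        """Project subjects (rows of an n×3P matrix) onto the modes."""
        return (np.asarray(data_matrix) - self.mean_vector) @ self.eigenvectors.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return self.mean_vector + np.asarray(scores) @ self.eigenvectors


def fit_modes(model) -> ShapeModeSet:
    """PCA of a correspondence model's GPA-aligned particle arrays.

    Accepts a :class:`~arthroshape.correspondence.CorrespondenceModel` or a
    plain n×3P matrix. The covariance uses the n−1 denominator and is
    diagonalized via SVD of the centred data (rank-revealing; at most n−1
    nonzero eigenvalues).
    """
    if hasattr(model, "particle_matrix"):
        data = model.particle_matrix(aligned=True).reshape(len(model.subject_ids), -1)
    else:
        data = np.asarray(model, dtype=np.float64)
    n = len(data)
    if n < 3:
        raise ValueError("PCA needs at least 3 subjects")
    mean = data.mean(axis=0)
    centred = data - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n - 1, data.shape[1])
    eigenvalues = np.maximum(s[:k] ** 2 / (n - 1), 0.0)
    eigenvectors = vt[:k]
    total = eigenvalues.sum()
    frac = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    modeset = ShapeModeSet(mean, eigenvalues, eigenvectors, frac, n)
    modeset.validate()
    return modeset


def parallel_analysis(data_matrix: np.ndarray, n_reps: int = 200,
                      percentile: float = 95.0, seed: int = 0) -> int:
    """Horn's parallel analysis: how many modes beat random data.

    The observed matrix is column-standardized and its correlation-matrix
    eigenvalues are compared, index by index, against the given percentile
    of eigenvalues from ``n_reps`` standard-normal matrices of the same
    shape (standardized identically). Mode i is retained iff its observed
    eigenvalue exceeds the null percentile; retention stops at the first
    failure. The percentile uses the conservative 'higher' order statistic.
    """
    data = np.asarray(data_matrix, dtype=np.float64)
    n, p = data.shape
    obs = _correlation_eigenvalues(data)
    if obs.max(initial=0.0) <= 0:
        return 0
    rng = np.random.default_rng(seed)
    k = len(obs)
    null = np.empty((n_reps, k))
    for r in range(n_reps):
        null[r] = _correlation_eigenvalues(rng.standard_normal((n, p)))[:k]
    thresholds = np.percentile(null, percentile, axis=0, method="higher")
    n_significant = 0
    for lam, thr in zip(obs, thresholds):
        if lam > thr:
            n_significant += 1
        else:
            break
    return n_significant


def _correlation_eigenvalues(data: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix via SVD of standardized data."""
    n = len(data)
    centred = data - data.mean(axis=0)
    sd = centred.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        return np.zeros(1)
    z = centred[:, keep] / sd[keep]
    s = np.linalg.svd(z, compute_uv=False)
    return s ** 2 / (n - 1)


def warp_mode(modeset: ShapeModeSet, mode_index: int, k_sd: float,
              template_mesh: SurfaceMesh,
              template_particles: np.ndarray) -> SurfaceMesh:
    """Warp the mean surface ±k SD along one mode.

    The particle displacement is k_sd·√λ·v reshaped to (P, 3), anchored at
    ``template_particles`` (normally the mean particles on the mean
    surface) and TPS-interpolated onto the template mesh vertices.
    """
    if not np.isfinite(k_sd):
        raise ValueError("k_sd must be finite")
    if mode_index >= len(modeset.eigenvalues):
        raise ValueError("mode_index out of range")
    lam = modeset.eigenvalues[mode_index]
    out = template_mesh.copy()
    out.subject_id = f"mode{mode_index}_{k_sd:+g}sd"
    if lam <= 0:
        if k_sd != 0:
            warnings.warn("zero-eigenvalue mode requested; returning the "
                          "mean surface", stacklevel=2)
        return out
    disp = (k_sd * np.sqrt(lam)
            * modeset.eigenvectors[mode_index]).reshape(-1, 3)
    if np.abs(disp).max(initial=0.0) == 0.0:
        return out
    out.vertices = out.vertices + tps_warp(np.asarray(template_particles),
                                           disp, out.vertices)
    return out


def mode_distance_map(mean_surface: SurfaceMesh,
                      warped_surface: SurfaceMesh) -> np.ndarray:
    """Per-vertex distance of the warped surface from the mean (mm).

    Surface-distance color-map field: for each vertex of the warped
    reconstruction, the unsigned closest-point distance to the mean surface.
    """
    return surface_to_surface_distance(warped_surface, mean_surface)


def mode_summary_rows(modeset: ShapeModeSet):
    """Rows for the mode-summary CSV (mode, eigenvalue, fraction, significant)."""
    nsig = modeset.n_significant or 0
    return [{"mode": i + 1,
             "eigenvalue": float(lam),
             "variance_fraction": float(frac),
             "significant": "yes" if i < nsig else "no"}
            for i, (lam, frac) in enumerate(zip(modeset.eigenvalues,
                                                modeset.variance_fraction))]
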