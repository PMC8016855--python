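"""Thin-plate-spline (3D biharmonic, kernel r) displacement interpolation.

Wraps :class:`scipy.interpolate.RBFInterpolator` with the linear kernel
φ(r) = r and zero smoothing, which is the exact-interpolation biharmonic
spline in 3D: particle displacements are reproduced exactly at the particle
sites and extended smoothly over the mesh.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RBFInterpolator


def tps_warp(anchor_points: np.ndarray, anchor_displacements: np.ndarray,
             query_points: np.ndarray) -> np.ndarray:
    """Interpolate per-anchor 3D displacements to the query points."""
    anchors = np.asarray(anchor_points, dtype=np.float64)
    disp = np.asarray(anchor_displacements, dtype=np.float64)
    if np.abs(disp).max(initial=0.0) == 0.0:
        return np.zeros((len(np.atleast_2d(query_points)), 3))
    interp = RBFInterpolator(anchors, disp, kernel="linear", smoothing=0.0,
                             degree=1)
    return interp(np.atleast_2d(np.asarray(query_points, dtype=np.float64)))
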