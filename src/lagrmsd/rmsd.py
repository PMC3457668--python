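"""Pairwise RMSD, optimal superposition, and the all-vs-all RMSD matrix.

The configurational distance between two frames is

    RMSD(a, b) = sqrt( (1/N) * sum_i ||x_i(b) - x_i(a)||^2 )

optionally after a weighted least-squares (Kabsch) superposition of frame b
onto frame a.  With per-atom weights both the superposition and the mean use
the normalized weights.  The all-vs-all matrix is computed lag-diagonal by
lag-diagonal with a single vectorized kernel, which makes it bit-identical
to the streaming lag averages computed without materializing the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import RMSDMatrix, Trajectory

__all__ = [
    "SuperpositionResult",
    "ReferenceCurves",
    "kabsch",
    "rmsd_pair",
    "rmsd_matrix",
    "reference_curves",
]


def _norm_weights(weights, n_atoms: int) -> np.ndarray:
    if weights is None:
        return np.full(n_atoms, 1.0 / n_atoms)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_atoms,):
        raise ValueError(f"weights must have shape ({n_atoms},), got {w.shape}")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    return w / w.sum()


def _check_pair(frame_a, frame_b):
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise ValueError("frames must have shape (n_atoms, 3)")
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"atom counts differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 1:
        raise ValueError("need at least one atom")
    return a, b


def _pairwise_unaligned(A: np.ndarray, B: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unaligned RMSD for stacked frame pairs A[m] vs B[m]; w normalized."""
    d = B - A
    return np.sqrt(np.einsum("mij,mij,i->m", d, d, w))


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition of a mobile frame onto a reference.

    ``rotation`` is a proper orthogonal 3x3 matrix and ``translation`` the
    vector such that ``rotation @ x + translation`` maps mobile coordinates
    onto the reference frame; ``rmsd_after`` is the weighted RMSD after the
    move.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_after: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class ReferenceCurves:
    """Per-frame RMSD curves against three reference configurations.

    ``idx_max`` is the "maximum outlier" (largest mean RMSD to all other
    frames), ``idx_min`` the "most central" frame; ties break to the
    smallest index.  Each curve is zero at its own reference frame.
    """

    per_frame_mean: np.ndarray
    idx_max: int
    idx_min: int
    curve_first: np.ndarray
    curve_max: np.ndarray
    curve_min: np.ndarray


def kabsch(reference, mobile, weights=None) -> SuperpositionResult:
    """Weighted least-squares superposition (reflections excluded).

    Degenerate geometries (single atom, collinear sets) fall back to the
    best rotation found rather than raising.
    """
    ref, mob = _check_pair(reference, mobile)
    w = _norm_weights(weights, ref.shape[0])
    ref_centroid = w @ ref
    mob_centroid = w @ mob
    ref_c = ref - ref_centroid
    mob_c = mob - mob_centroid
    tiny = 1e-30
    if ref.shape[0] < 2 or (ref_c * ref_c).sum() < tiny or (mob_c * mob_c).sum() < tiny:
        R = np.eye(3)  # rotation undetermined; translation alone is optimal
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-unique optimum for degenerate sets
            rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
        R = rot.as_matrix()
    translation = ref_centroid - R @ mob_centroid
    moved = mob @ R.T + translation
    rmsd_after = float(_pairwise_unaligned(ref[None], moved[None], w)[0])
    return SuperpositionResult(rotation=R, translation=translation, rmsd_after=rmsd_after)


def rmsd_pair(frame_a, frame_b, align: bool = True, weights=None) -> float:
    """RMSD between two frames, optionally after Kabsch superposition."""
    a, b = _check_pair(frame_a, frame_b)
    w = _norm_weights(weights, a.shape[0])
    if align:
        return kabsch(a, b, weights=weights).rmsd_after
    return float(_pairwise_unaligned(a[None], b[None], w)[0])


def rmsd_matrix(traj: Trajectory, align: bool = True, weights=None) -> RMSDMatrix:
    """All-vs-all RMSD matrix of a trajectory.

    Each unordered pair is computed once.  In the unaligned case entire
    lag diagonals are evaluated by the vectorized kernel; aligned matrices
    superpose each pair individually.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if weights is None:
        weights = traj.weights
    n = traj.n_frames
    w = _norm_weights(weights, traj.n_atoms)
    values = np.zeros((n, n))
    if align:
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = kabsch(
                    traj.coords[i], traj.coords[j], weights=weights
                ).rmsd_after
    else:
        idx = np.arange(n)
        for k in range(1, n):
            vals = _pairwise_unaligned(traj.coords[:-k], traj.coords[k:], w)
            values[idx[: n - k], idx[k:]] = vals
            values[idx[k:], idx[: n - k]] = vals
    return RMSDMatrix(values=values, times=traj.times, unit=traj.unit)


def reference_curves(matrix: RMSDMatrix) -> ReferenceCurves:
    """RMSD curves against the first, most-outlying and most-central frame.

    The mean RMSD of frame *j* to all other frames identifies the maximum
    outlier (argmax) and the most central configuration (argmin).
    """
    v = matrix.values
    n = matrix.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames")
    per_frame_mean = v.sum(axis=0) / (n - 1)
    idx_max = int(np.argmax(per_frame_mean))
    idx_min = int(np.argmin(per_frame_mean))
    return ReferenceCurves(
        per_frame_mean=per_frame_mean,
        idx_max=idx_max,
        idx_min=idx_min,
        curve_first=v[0].copy(),
        curve_max=v[idx_max].copy(),
        curve_min=v[idx_min].copy(),
    )
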