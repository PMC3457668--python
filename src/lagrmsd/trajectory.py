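"""Core data containers: coordinate trajectories and all-vs-all RMSD matrices.

Times are carried in picoseconds; lengths in the unit recorded on the
container (Å by default).  Both containers validate their structural
invariants on construction so downstream stages can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory", "RMSDMatrix", "DEFAULT_LENGTH_UNIT"]

DEFAULT_LENGTH_UNIT = "angstrom"

#: relative tolerance for declaring a frame spacing uniform
_UNIFORM_RTOL = 1e-6


def _as_times(times, n: int) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.shape != (n,):
        raise ValueError(f"times must have shape ({n},), got {t.shape}")
    if n > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("frame times must be strictly increasing")
    return t


def _uniform_spacing(times: np.ndarray) -> float:
    """Median frame spacing; raises if the spacing is not uniform."""
    if times.size < 2:
        raise ValueError("need at least 2 frames to define a frame spacing")
    dt = np.diff(times)
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _UNIFORM_RTOL * med:
        raise ValueError("frame spacing is not uniform")
    return med


@dataclass
class Trajectory:
    """Ordered frames of atomic coordinates with per-frame times.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)``, float64.
    times
        Per-frame times in ps, strictly increasing.
    atom_labels
        One identifier per atom (e.g. PDB atom names).
    weights
        Optional positive per-atom masses/weights used for superposition
        and for the RMSD average.
    unit
        Length-unit tag carried through to every derived quantity.
    """

    coords: np.ndarray
    times: np.ndarray
    atom_labels: np.ndarray | None = None
    weights: np.ndarray | None = None
    unit: str = DEFAULT_LENGTH_UNIT

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.n_atoms < 1:
            raise ValueError("every frame needs at least one atom")
        self.times = _as_times(self.times, self.n_frames)
        if self.atom_labels is None:
            self.atom_labels = np.array([f"A{i}" for i in range(self.n_atoms)])
        else:
            self.atom_labels = np.asarray(self.atom_labels)
            if self.atom_labels.shape != (self.n_atoms,):
                raise ValueError("atom_labels must have one entry per atom")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_atoms,):
                raise ValueError("weights must have one entry per atom")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def spacing_ps(self) -> float:
        """Uniform frame spacing in ps (raises for non-uniform times)."""
        return _uniform_spacing(self.times)

    @property
    def duration_ps(self) -> float:
        return float(self.times[-1] - self.times[0])

    def select(self, labels) -> "Trajectory":
        """Sub-trajectory restricted to atoms whose label is in *labels*."""
        wanted = {str(x) for x in labels}
        mask = np.array([str(l) in wanted for l in self.atom_labels])
        if not mask.any():
            raise ValueError(f"selection {sorted(wanted)} matches no atoms")
        return Trajectory(
            coords=self.coords[:, mask, :],
            times=self.times,
            atom_labels=self.atom_labels[mask],
            weights=None if self.weights is None else self.weights[mask],
            unit=self.unit,
        )


@dataclass
class RMSDMatrix:
    """Symmetric all-vs-all configurational distance matrix.

    ``values[i, j]`` is the RMSD between frames *i* and *j*, in the same
    length unit as the coordinates the matrix came from.
    """

    values: np.ndarray
    times: np.ndarray
    unit: str = DEFAULT_LENGTH_UNIT

    #: relative symmetry tolerance of the invariant
    SYM_RTOL = 1e-9

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RMSD matrix must be square, got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("RMSD matrix entries must be nonnegative")
        scale = max(float(np.max(np.abs(v))), 1.0)
        if np.max(np.abs(v - v.T)) > self.SYM_RTOL * scale:
            raise ValueError("RMSD matrix is not symmetric")
        if np.any(np.abs(np.diagonal(v)) > 1e-9 * scale):
            raise ValueError("RMSD matrix diagonal must be zero")
        self.values = v
        self.times = _as_times(self.times, v.shape[0])

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def spacing_ps(self) -> float:
        return _uniform_spacing(self.times)

    @property
    def duration_ps(self) -> float:
        return float(self.times[-1] - self.times[0])
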