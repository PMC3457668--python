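"""Lag schedules and lagged mean-RMSD curves.

The average RMSD between all frame pairs separated by a fixed time lag,
RMSD(Δt), is the basic observable of the convergence diagnostic.  Lags are
sampled densely at short Δt (where the curve rises fastest) and
geometrically thereafter, up to half the length of the analysis window —
this puts extra fitting weight on the initial rise without reweighting
residuals.  The analysis window starts at a configurable offset time so the
whole construction can be repeated with the equilibration phase excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rmsd import _norm_weights, _pairwise_unaligned, kabsch
from .trajectory import RMSDMatrix, Trajectory

__all__ = ["LagSchedule", "LagCurve", "build_lag_schedule", "lagged_mean_rmsd"]

#: dense head covers this fraction of the window by default
DEFAULT_DENSE_FRACTION = 0.05
DEFAULT_SPARSE_COUNT = 40


@dataclass
class LagSchedule:
    """Strictly increasing frame-lag integers for one analysis window."""

    lag_indices: np.ndarray
    window_frames: int

    def __post_init__(self) -> None:
        lags = np.asarray(self.lag_indices, dtype=int)
        if lags.size == 0:
            raise ValueError("lag schedule is empty")
        if np.any(lags < 1) or np.any(np.diff(lags) <= 0):
            raise ValueError("lag indices must be strictly increasing and >= 1")
        if lags[-1] > self.window_frames // 2:
            raise ValueError(
                f"max lag {lags[-1]} exceeds half the window ({self.window_frames // 2})"
            )
        self.lag_indices = lags


@dataclass
class LagCurve:
    """Mean RMSD as a function of time lag for one analysis window."""

    lags_ps: np.ndarray
    mean_rmsd: np.ndarray
    sd_rmsd: np.ndarray
    n_pairs: np.ndarray
    t_offset_ps: float
    unit: str = "angstrom"

    def to_records(self) -> list[dict]:
        return [
            {
                "lag_ps": float(l),
                "mean_rmsd": float(m),
                "sd_rmsd": float(s),
                "n_pairs": int(n),
                "t_offset_ps": float(self.t_offset_ps),
            }
            for l, m, s, n in zip(self.lags_ps, self.mean_rmsd, self.sd_rmsd, self.n_pairs)
        ]


def build_lag_schedule(
    window_frames: int,
    dense_upto: int | None = None,
    dense_step: int = 1,
    sparse_count: int = DEFAULT_SPARSE_COUNT,
) -> LagSchedule:
    """Dense arithmetic head plus geometric tail, capped at window/2.

    Lags run {dense_step, 2·dense_step, …, dense_upto} followed by
    ``sparse_count`` geometrically spaced lags up to ``floor(window/2)``,
    which is always included.
    """
    if window_frames < 4:
        raise ValueError(f"window of {window_frames} frames is too small (need >= 4)")
    max_lag = window_frames // 2
    if dense_upto is None:
        dense_upto = max(dense_step, round(DEFAULT_DENSE_FRACTION * window_frames))
        dense_upto = min(dense_upto, max_lag - 1) if max_lag > 1 else 0
    if dense_step < 1 or sparse_count < 1:
        raise ValueError("dense_step and sparse_count must be >= 1")
    if dense_upto >= max_lag:
        raise ValueError(f"dense_upto ({dense_upto}) must be < window/2 ({max_lag})")
    dense = np.arange(dense_step, dense_upto + 1, dense_step)
    start = max(dense_upto, 1)
    sparse = np.unique(
        np.rint(np.geomspace(start, max_lag, sparse_count + 1)).astype(int)
    )
    sparse = sparse[sparse > dense_upto]
    lags = np.unique(np.concatenate([dense, sparse, [max_lag]]))
    lags = lags[(lags >= 1) & (lags <= max_lag)]
    if lags.size == 0:
        raise ValueError("schedule parameters produce no lags")
    return LagSchedule(lag_indices=lags, window_frames=window_frames)


def _window_start(times: np.ndarray, t_offset_ps: float) -> int:
    duration = float(times[-1] - times[0])
    if t_offset_ps < 0:
        raise ValueError("t_offset_ps must be nonnegative")
    if t_offset_ps > duration / 2:
        raise ValueError(
            f"t_offset {t_offset_ps} ps exceeds half the trajectory ({duration / 2} ps)"
        )
    return int(np.searchsorted(times, times[0] + t_offset_ps - 1e-9 * max(1.0, abs(t_offset_ps))))


def lagged_mean_rmsd(
    source: Trajectory | RMSDMatrix,
    schedule: LagSchedule | None = None,
    t_offset_ps: float = 0.0,
    align: bool = False,
    weights=None,
) -> LagCurve:
    """Mean RMSD per scheduled lag over the window starting at ``t_offset_ps``.

    Accepts either a precomputed :class:`RMSDMatrix` or a
    :class:`Trajectory`; the latter is evaluated in streaming mode (lag
    diagonals computed on the fly, never materializing the full matrix)
    with results bit-identical to the matrix route.  All admissible frame
    pairs at each scheduled lag enter the average.
    """
    times = source.times
    n = times.shape[0]
    start = _window_start(times, t_offset_ps)
    window = n - start
    if window < 4:
        raise ValueError(f"window too small: {window} frames past t_offset (need >= 4)")
    if schedule is None:
        schedule = build_lag_schedule(window)
    elif schedule.window_frames != window:
        raise ValueError(
            f"schedule built for window of {schedule.window_frames} frames, "
            f"but t_offset leaves {window}"
        )
    spacing = source.spacing_ps

    is_matrix = isinstance(source, RMSDMatrix)
    if not is_matrix:
        w = _norm_weights(traj_weights(source, weights), source.n_atoms)

    means, sds, counts = [], [], []
    for k in schedule.lag_indices:
        if is_matrix:
            i = np.arange(start, n - k)
            vals = source.values[i, i + k]
        elif align:
            vals = np.array(
                [
                    kabsch(source.coords[i], source.coords[i + k],
                           weights=traj_weights(source, weights)).rmsd_after
                    for i in range(start, n - k)
                ]
            )
        else:
            vals = _pairwise_unaligned(
                source.coords[start : n - k], source.coords[start + k : n], w
            )
        means.append(np.mean(vals))
        sds.append(np.std(vals, ddof=1) if vals.size > 1 else 0.0)
        counts.append(vals.size)
    return LagCurve(
        lags_ps=schedule.lag_indices * spacing,
        mean_rmsd=np.array(means),
        sd_rmsd=np.array(sds),
        n_pairs=np.array(counts, dtype=int),
        t_offset_ps=float(t_offset_ps),
        unit=source.unit,
    )


def traj_weights(traj: Trajectory, weights):
    """Explicit weights win over the trajectory's own."""
    return weights if weights is not None else traj.weights
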