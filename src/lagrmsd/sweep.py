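"""Offset sweep: Hill fits over a grid of equilibration offsets.

Repeating the lag analysis while discarding a growing initial portion of
the trajectory (offset t_offset ∈ [0, t_max/2]) exposes the influence of
the starting configuration: as long as the fitted parameters still drift
with t_offset, the sampled trajectory has not converged.  The fitted
plateaus a(t_offset) are extrapolated to t_offset = ∞ with the
monoexponential decay model, and a quantitative stationarity verdict is
derived from the relative spread of a and τ over the tail of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fitting import HillFit, OffsetDecayFit, fit_hill, fit_offset_decay
from .lags import LagCurve, LagSchedule, build_lag_schedule, lagged_mean_rmsd
from .trajectory import RMSDMatrix, Trajectory

__all__ = [
    "OffsetSweepResult",
    "sweep_offsets",
    "extrapolate_plateau",
    "assess_stationarity",
    "DEFAULT_N_OFFSETS",
    "DEFAULT_REL_TOL",
    "DEFAULT_TAIL_FRACTION",
]

DEFAULT_N_OFFSETS = 11
DEFAULT_REL_TOL = 0.05
DEFAULT_TAIL_FRACTION = 0.5

STATIONARY = "stationary"
NOT_STATIONARY = "not_stationary"
INDETERMINATE = "indeterminate"


@dataclass
class OffsetSweepResult:
    """Hill fits and lag curves across the offset grid, plus verdict."""

    offsets_ps: np.ndarray
    fits: list[HillFit]
    curves: list[LagCurve]
    decay: OffsetDecayFit | None = None
    verdict: str | None = None
    verdict_metrics: dict = field(default_factory=dict)

    @property
    def converged_mask(self) -> np.ndarray:
        return np.array([f.converged for f in self.fits], dtype=bool)

    def to_records(self) -> list[dict]:
        out = []
        for off, fit in zip(self.offsets_ps, self.fits):
            rec = {"t_offset_ps": float(off)}
            rec.update(fit.to_record())
            out.append(rec)
        return out


def sweep_offsets(
    source: Trajectory | RMSDMatrix,
    n_offsets: int = DEFAULT_N_OFFSETS,
    schedule_params: dict | None = None,
    align: bool = False,
    weights=None,
    schedule_mode: str = "per_window",
) -> OffsetSweepResult:
    """Lag analysis + Hill fit at each offset of an even grid on [0, t_max/2].

    With ``schedule_mode="per_window"`` the lag schedule is rebuilt on each
    offset window (maximum lag = half the *windowed* length) from
    ``schedule_params`` (keys ``dense_upto``, ``dense_step``,
    ``sparse_count``).  With ``"fixed"`` one schedule is built for the
    smallest (largest-offset) window and reused at every offset, so all
    offsets are compared with an identical lag estimator and differences in
    the fitted parameters reflect the data alone.  Failed fits are retained
    with ``converged=False``.
    """
    if n_offsets < 4:
        raise ValueError("need at least 4 offsets")
    if schedule_mode not in ("per_window", "fixed"):
        raise ValueError(f"unknown schedule_mode {schedule_mode!r}")
    times = source.times
    t_max = float(times[-1] - times[0])
    offsets = np.linspace(0.0, t_max / 2.0, n_offsets)
    # the largest offset must leave a usable window
    n_last = times.size - int(np.searchsorted(times, times[0] + offsets[-1] - 1e-9))
    if n_last < 8:
        raise ValueError(
            f"trajectory too short: largest offset window has {n_last} frames (need >= 8)"
        )
    params = dict(schedule_params or {})
    fixed_lags = (
        build_lag_schedule(n_last, **params).lag_indices
        if schedule_mode == "fixed"
        else None
    )
    fits, curves = [], []
    for off in offsets:
        start = int(np.searchsorted(times, times[0] + off - 1e-9 * max(1.0, off)))
        window = times.size - start
        if fixed_lags is None:
            schedule = build_lag_schedule(window, **params)
        else:
            schedule = LagSchedule(lag_indices=fixed_lags, window_frames=window)
        curve = lagged_mean_rmsd(source, schedule, t_offset_ps=off, align=align,
                                 weights=weights)
        fits.append(fit_hill(curve))
        curves.append(curve)
    return OffsetSweepResult(offsets_ps=offsets, fits=fits, curves=curves)


def extrapolate_plateau(sweep: OffsetSweepResult, weighted: bool = True) -> OffsetDecayFit:
    """Fit the offset-decay model to the converged plateau estimates.

    Weighted by each plateau's standard error when all are finite and
    positive.  Stores the fit on ``sweep.decay`` and returns it.
    """
    mask = sweep.converged_mask
    n_conv = int(mask.sum())
    if n_conv < 4:
        raise ValueError(f"need >= 4 converged Hill fits, got {n_conv}")
    offsets = sweep.offsets_ps[mask]
    plateaus = np.array([f.a for f, m in zip(sweep.fits, mask) if m])
    ses = np.array([f.se_a for f, m in zip(sweep.fits, mask) if m])
    use_ses = ses if (weighted and np.all(np.isfinite(ses)) and np.all(ses > 0)) else None
    decay = fit_offset_decay(offsets, plateaus, plateau_ses=use_ses)
    sweep.decay = decay
    return decay


def assess_stationarity(
    sweep: OffsetSweepResult,
    rel_tol: float = DEFAULT_REL_TOL,
    tail_fraction: float = DEFAULT_TAIL_FRACTION,
) -> tuple[str, dict]:
    """Verdict on whether the lagged-RMSD shape has stopped changing.

    Over the final ``tail_fraction`` of converged fits, the maximum
    relative deviation of the plateau a and of the half-saturation lag τ
    from their tail medians is computed; the sweep is called stationary
    only if both stay below ``rel_tol``.  Fewer than 4 converged fits give
    an indeterminate verdict.  Metrics are always attached to the sweep.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    mask = sweep.converged_mask
    n_conv = int(mask.sum())
    metrics: dict = {
        "n_converged": n_conv,
        "rel_tol": float(rel_tol),
        "tail_fraction": float(tail_fraction),
        "max_rel_dev_a": float("nan"),
        "max_rel_dev_tau": float("nan"),
    }
    if n_conv < 4:
        sweep.verdict, sweep.verdict_metrics = INDETERMINATE, metrics
        return INDETERMINATE, metrics
    a_vals = np.array([f.a for f, m in zip(sweep.fits, mask) if m])
    tau_vals = np.array([f.tau for f, m in zip(sweep.fits, mask) if m])
    n_tail = max(2, int(np.ceil(tail_fraction * n_conv)))
    a_tail, tau_tail = a_vals[-n_tail:], tau_vals[-n_tail:]

    def max_rel_dev(x):
        med = float(np.median(x))
        if med == 0:
            return float("inf") if np.any(x != 0) else 0.0
        return float(np.max(np.abs(x - med)) / abs(med))

    dev_a, dev_tau = max_rel_dev(a_tail), max_rel_dev(tau_tail)
    metrics["max_rel_dev_a"], metrics["max_rel_dev_tau"] = dev_a, dev_tau
    verdict = STATIONARY if (dev_a < rel_tol and dev_tau < rel_tol) else NOT_STATIONARY
    sweep.verdict, sweep.verdict_metrics = verdict, metrics
    return verdict, metrics
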