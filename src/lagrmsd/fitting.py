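"""Nonlinear models for the lagged-RMSD analysis.

Two models are fitted by bounded least squares:

* the Hill saturation model  RMSD(Δt) = a·Δt^γ / (τ^γ + Δt^γ),
  with plateau ``a``, half-saturation lag ``τ`` (the model equals a/2 at
  Δt = τ by construction) and sigmoidicity ``γ``;
* the monoexponential offset decay  a(t_offset) = a0 + β·exp(−λ·t_offset),
  whose intercept a0 extrapolates the plateau to infinite equilibration
  time — the RMSD between totally unrelated configurations.

Standard errors are the usual asymptotic ones from the Jacobian at the
optimum, cov = rss/(n−p) · (JᵀJ)⁻¹.  Degenerate inputs (flat curves,
optimizer failures) yield results flagged ``converged=False`` instead of
exceptions so that a sweep over many windows survives individual failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillFit",
    "OffsetDecayFit",
    "hill_eval",
    "fit_hill",
    "exp_offset_eval",
    "fit_offset_decay",
]

_FIT_TOL = 1e-10
_MAX_NFEV = 10_000


def hill_eval(a: float, tau: float, gamma: float, dt) -> float | np.ndarray:
    """Hill saturation model; 0 at dt = 0, asymptote ``a`` as dt → ∞."""
    if a <= 0 or tau <= 0 or gamma <= 0:
        raise ValueError("Hill parameters a, tau, gamma must be positive")
    dt_arr = np.asarray(dt, dtype=float)
    if np.any(dt_arr < 0):
        raise ValueError("dt must be nonnegative")
    # a / (1 + (tau/dt)^gamma) is overflow-safe for dt >> tau
    with np.errstate(divide="ignore"):
        out = np.where(dt_arr > 0, a / (1.0 + (tau / np.where(dt_arr > 0, dt_arr, 1.0)) ** gamma), 0.0)
    return float(out) if np.isscalar(dt) or out.ndim == 0 else out


def exp_offset_eval(a0: float, beta: float, lam: float, t_offset) -> float | np.ndarray:
    """Monoexponential decay of the fitted plateau with the analysis offset."""
    if lam <= 0:
        raise ValueError("decay rate lam must be positive")
    t = np.asarray(t_offset, dtype=float)
    out = a0 + beta * np.exp(-lam * t)
    return float(out) if np.isscalar(t_offset) or out.ndim == 0 else out


@dataclass
class HillFit:
    """Fitted Hill parameters with asymptotic standard errors."""

    a: float
    tau: float
    gamma: float
    se_a: float
    se_tau: float
    se_gamma: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def predict(self, dt):
        return hill_eval(self.a, self.tau, self.gamma, dt)

    def to_record(self) -> dict:
        return {
            "a": self.a, "tau": self.tau, "gamma": self.gamma,
            "se_a": self.se_a, "se_tau": self.se_tau, "se_gamma": self.se_gamma,
            "rss": self.rss, "converged": self.converged, "n_points": self.n_points,
        }


@dataclass
class OffsetDecayFit:
    """Fitted offset-decay parameters with asymptotic standard errors."""

    a0: float
    beta: float
    lam: float
    se_a0: float
    se_beta: float
    se_lam: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def predict(self, t_offset):
        return exp_offset_eval(self.a0, self.beta, max(self.lam, np.finfo(float).tiny), t_offset)

    def to_record(self) -> dict:
        return {
            "a0": self.a0, "beta": self.beta, "lam": self.lam,
            "se_a0": self.se_a0, "se_beta": self.se_beta, "se_lam": self.se_lam,
            "rss": self.rss, "converged": self.converged, "n_points": self.n_points,
        }


def _asymptotic_se(jac: np.ndarray, rss: float, n: int, p: int) -> np.ndarray:
    dof = n - p
    if dof <= 0:
        return np.full(p, np.nan)
    jtj = jac.T @ jac
    try:
        cov = rss / dof * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    d = np.diagonal(cov)
    return np.sqrt(np.where(d >= 0, d, np.nan))


def fit_hill(curve, init=None, bounds=None, weighted: bool = False) -> HillFit:
    """Least-squares Hill fit to a lag curve.

    ``curve`` is a :class:`~lagrmsd.lags.LagCurve` or any object with
    ``lags_ps`` and ``mean_rmsd``.  Default initialization: a = max of the
    curve, τ = first lag where the curve exceeds half its maximum, γ = 1.
    ``weighted`` applies inverse-variance weights from ``sd_rmsd`` where
    positive.
    """
    lags = np.asarray(curve.lags_ps, dtype=float)
    y = np.asarray(curve.mean_rmsd, dtype=float)
    n = lags.size
    nan = float("nan")
    if np.unique(lags).size < 4:
        return HillFit(nan, nan, nan, nan, nan, nan, nan, False, n,
                       "need >= 4 distinct lags")
    ymax = float(np.max(y))
    if np.unique(y).size < 2 or ymax <= 0:
        return HillFit(nan, nan, nan, nan, nan, nan, 0.0, False, n,
                       "flat or nonpositive curve")

    if init is None:
        above = lags[y >= 0.5 * ymax]
        tau0 = float(above[0]) if above.size else float(np.median(lags))
        init = (ymax, max(tau0, np.finfo(float).tiny), 1.0)
    if bounds is None:
        eps = 1e-12
        bounds = ([eps, eps, eps], [np.inf, np.inf, np.inf])

    if weighted:
        sd = np.asarray(getattr(curve, "sd_rmsd", np.ones(n)), dtype=float)
        wgt = np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0), 1.0)
    else:
        wgt = np.ones(n)

    def resid(p):
        return (y - hill_eval(p[0], p[1], p[2], lags)) * wgt

    res = least_squares(
        resid, x0=np.asarray(init, dtype=float), bounds=bounds,
        xtol=_FIT_TOL, ftol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=_MAX_NFEV,
    )
    rss = float(np.sum(res.fun**2))
    se = _asymptotic_se(res.jac, rss, n, 3)
    a, tau, gamma = map(float, res.x)
    ok = bool(res.success and np.all(np.isfinite(res.x)) and min(a, tau, gamma) > 0)
    return HillFit(a, tau, gamma, float(se[0]), float(se[1]), float(se[2]),
                   rss, ok, n, res.message)


def fit_offset_decay(offsets_ps, plateaus, plateau_ses=None) -> OffsetDecayFit:
    """Least-squares monoexponential fit of plateau values vs offset.

    Default initialization: a0 = last plateau, β = first − last,
    λ = 1/(offset range).  Optional inverse-variance weighting by the
    plateaus' standard errors.  β is reported as fitted — a non-decaying
    series yields β ≤ 0 rather than a clamped value.
    """
    t = np.asarray(offsets_ps, dtype=float)
    y = np.asarray(plateaus, dtype=float)
    n = t.size
    if n < 4:
        raise ValueError(f"need >= 4 offset points, got {n}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("offsets must be strictly increasing")

    t_range = float(t[-1] - t[0])
    init = np.array([y[-1], y[0] - y[-1], 1.0 / t_range if t_range > 0 else 1.0])
    if init[1] == 0.0:
        init[1] = 1e-8 * max(abs(y[-1]), 1.0)  # avoid a zero-gradient start
    eps = np.finfo(float).tiny
    bounds = ([-np.inf, -np.inf, eps], [np.inf, np.inf, np.inf])

    if plateau_ses is not None:
        ses = np.asarray(plateau_ses, dtype=float)
        if np.all(np.isfinite(ses)) and np.all(ses > 0):
            wgt = 1.0 / ses
        else:
            wgt = np.ones(n)
    else:
        wgt = np.ones(n)

    def resid(p):
        return (y - (p[0] + p[1] * np.exp(-p[2] * t))) * wgt

    res = least_squares(
        resid, x0=init, bounds=bounds,
        xtol=_FIT_TOL, ftol=_FIT_TOL, gtol=_FIT_TOL, max_nfev=_MAX_NFEV,
    )
    rss = float(np.sum(res.fun**2))
    se = _asymptotic_se(res.jac, rss, n, 3)
    a0, beta, lam = map(float, res.x)
    ok = bool(res.success and np.all(np.isfinite(res.x)))
    msg = res.message
    # lam -> 0 makes exp(-lam t) ~ 1 - lam t over the grid: a0 and beta are
    # then collinear and the extrapolation meaningless; flag, don't raise.
    if ok and t_range > 0 and lam * t_range < 0.05 and abs(beta) > 1e-8 * max(abs(a0), 1.0):
        ok = False
        msg = "decay rate unresolved over the offset range (a0/beta collinear)"
    return OffsetDecayFit(a0, beta, lam, float(se[0]), float(se[1]), float(se[2]),
                          rss, ok, n, msg)
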