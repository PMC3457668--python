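"""Synthetic trajectories with known statistics.

Atomic fluctuations are modeled as independent Ornstein–Uhlenbeck (OU)
processes per coordinate: mean-reverting Gaussian noise with stationary
standard deviation σ and relaxation time τ_c, advanced with the *exact*
discrete-time update

    x[k+1] = ρ·x[k] + σ·sqrt(1 − ρ²)·ξ,   ρ = exp(−Δt/τ_c),

so the closed-form lagged RMSD

    RMSD(Δt) = sqrt( 6σ²·(1 − exp(−Δt/τ_c)) )

(the large-N limit for 3-D atoms without superposition, plateau √6·σ)
holds at any frame spacing with no integrator bias.  Two departures from
stationarity can be switched on: an equilibration transient (all
coordinates start displaced by a fixed magnitude with random sign, then
relax) and a uniform linear drift along x (RMSD then grows without bound —
the signature of a run that is not long enough).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import hill_eval
from .lags import LagCurve
from .trajectory import DEFAULT_LENGTH_UNIT, Trajectory

__all__ = [
    "OUConfig",
    "generate_ou_trajectory",
    "expected_lag_rmsd_ou",
    "generate_hill_lagcurve",
]


@dataclass
class OUConfig:
    """Parameters of the synthetic OU trajectory generator.

    Defaults give a stationary 200-atom, 5 ns run at 1 ps spacing with
    σ = 1 Å and τ_c = 100 ps.  ``init_displacement`` (in length units)
    starts every coordinate off-equilibrium for transient runs;
    ``drift_velocity`` (length unit per frame) adds a uniform drift.
    """

    n_atoms: int = 200
    sigma: float = 1.0
    tau_c: float = 100.0
    dt_ps: float = 1.0
    n_frames: int = 5000
    seed: int = 0
    init_displacement: float | None = None
    drift_velocity: float | None = None
    unit: str = DEFAULT_LENGTH_UNIT

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.sigma <= 0 or self.tau_c <= 0 or self.dt_ps <= 0:
            raise ValueError("sigma, tau_c and dt_ps must be positive")


def generate_ou_trajectory(config: OUConfig) -> Trajectory:
    """Exact-discretization OU trajectory; same seed ⇒ bit-identical output."""
    rng = np.random.default_rng(config.seed)
    shape = (config.n_atoms, 3)
    rho = np.exp(-config.dt_ps / config.tau_c)
    kick = config.sigma * np.sqrt(1.0 - rho * rho)
    if config.init_displacement is not None:
        signs = rng.integers(0, 2, size=shape) * 2 - 1
        x = config.init_displacement * signs.astype(float)
    else:
        x = config.sigma * rng.standard_normal(shape)
    coords = np.empty((config.n_frames, *shape))
    coords[0] = x
    for k in range(1, config.n_frames):
        x = rho * x + kick * rng.standard_normal(shape)
        coords[k] = x
    if config.drift_velocity is not None:
        coords[:, :, 0] += config.drift_velocity * np.arange(config.n_frames)[:, None]
    times = np.arange(config.n_frames) * config.dt_ps
    return Trajectory(coords=coords, times=times, unit=config.unit)


def expected_lag_rmsd_ou(sigma: float, tau_c: float, dt_ps) -> float | np.ndarray:
    """Closed-form lagged RMSD of the stationary OU model (no superposition)."""
    if sigma <= 0 or tau_c <= 0:
        raise ValueError("sigma and tau_c must be positive")
    dt = np.asarray(dt_ps, dtype=float)
    out = np.sqrt(6.0 * sigma**2 * (1.0 - np.exp(-dt / tau_c)))
    return float(out) if np.isscalar(dt_ps) or out.ndim == 0 else out


def generate_hill_lagcurve(
    a: float,
    tau: float,
    gamma: float,
    lags_ps,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_pairs: int = 100,
) -> LagCurve:
    """Lag curve sampled from the Hill model plus seeded Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    lags = np.asarray(lags_ps, dtype=float)
    if lags.size == 0 or np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lags_ps must be strictly increasing positives")
    y = np.asarray(hill_eval(a, tau, gamma, lags), dtype=float)
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(lags.size)
    return LagCurve(
        lags_ps=lags,
        mean_rmsd=y,
        sd_rmsd=np.full(lags.size, noise_sd),
        n_pairs=np.full(lags.size, n_pairs, dtype=int),
        t_offset_ps=0.0,
    )
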