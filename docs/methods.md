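# Methods

## The diagnostic

Let x(t₁), …, x(tₙ) be the frames of an MD trajectory with uniform spacing
Δt_config. For every pair of frames separated by a lag Δt = t_j − t_i the
configurational distance is the RMSD of eq. form `sqrt(mean_i ||x_i(b) −
x_i(a)||²)`, optionally after an optimal rigid-body superposition. The
lagged mean curve

    RMSD̄(Δt) = mean over all admissible pairs at lag Δt

is a stable, reference-free summary: small lags compare near-identical
configurations, large lags compare configurations that should be
statistically unrelated if the run samples a stationary ensemble. The
curve is computed for lags up to half the length of the analysis window,
and the analysis window itself starts at an offset t_offset that discards
the initial, initial-structure-biased part of the run.

Three fitted quantities summarize each window: the Hill saturation model
`a·Δtᵞ/(τᵞ+Δtᵞ)` gives the plateau `a` (unrelated-configuration
distance), the half-saturation lag `τ` (decorrelation timescale) and the
sigmoidicity `γ`. Sweeping t_offset over [0, t_max/2] and fitting
`a(t_offset) = a₀ + β·e^(−λ·t_offset)` extrapolates the plateau to
infinite equilibration time. The operational verdict: over the final half
of the converged fits, if the maximum relative deviation of both `a` and
`τ` from their tail medians is below 5 % the sampled window is declared
`stationary`; otherwise `not_stationary`; with fewer than four converged
fits, `indeterminate`. Both thresholds (`rel_tol`, `tail_fraction`) are
explicit configuration and are reported next to the verdict — the verdict
is never more precise than the tolerance that produced it.

## Estimator choices that matter

**Lag schedule.** Lags are arithmetic (`dense_step`) up to `dense_upto`,
then geometric (`sparse_count` points) up to half the window. The dense
head gives the initial rise of the curve enough weight in an *unweighted*
least-squares fit; residuals are not reweighted (an inverse-variance mode
exists but is off by default). Defaults: dense head covering 5 % of the
window with step 1, 40 geometric tail points.

**Per-window vs fixed schedules.** When the schedule is rebuilt on each
offset window ("per_window", the default), the maximum lag shrinks as the
window shrinks, and the Hill fit's plateau bias (below) then *varies*
across offsets: on perfectly stationary synthetic data the fitted `a`
drifts upward by several percent and `τ` by >10 % over the grid — an
estimator artifact that can masquerade as non-stationarity. The "fixed"
mode builds one schedule on the smallest (largest-offset) window and
reuses it everywhere, so every offset is measured with the identical
estimator and parameter trends reflect the data alone. Cross-offset
comparisons — the stationarity verdict and the a₀ extrapolation — should
use the fixed mode; the per-window mode maximizes lag coverage when only
a single window is analyzed.

**Hill plateau bias.** The Hill function approaches its plateau
polynomially (like 1 − (τ/Δt)ᵞ) while an exponentially decorrelating
process approaches it exponentially. Fitted to such data the plateau `a`
therefore overshoots systematically; the overshoot shrinks as the
maximum lag grows relative to the relaxation time (measured on noise-free
curves: ≈ +19 % at max lag 5 τ_c, ≈ +10 % at 10 τ_c, ≈ +3 % at 100 τ_c,
with a dense head reaching ≈ 4 τ_c roughly halving these numbers). This
is a property of the model family, not a defect of the optimizer; it is
why quantitative plateau estimates need max lag ≳ 10 τ_c, and why the
fixed-schedule mode matters for offset sweeps. Real MD curves, shaped by
a spectrum of relaxation times, are typically closer to the Hill form
than the single-timescale synthetic worst case used here.

**Fitting.** Both models are fitted with bounded derivative-based least
squares (SciPy `least_squares`, trf), tolerances 1e-10, at most 10⁴
evaluations; Hill parameters are constrained positive through bounds.
Initialization: Hill — a = curve maximum, τ = first lag exceeding half
the maximum, γ = 1; decay — a₀ = last plateau, β = first − last,
λ = 1/offset-range. Standard errors are asymptotic,
cov = rss/(n−p)·(JᵀJ)⁻¹. Degenerate inputs (flat curves, < 4 distinct
lags) return results flagged `converged=False` instead of raising, so a
sweep survives individual failures. The decay fit additionally flags
λ·offset-range < 0.05 as unresolved: in that regime e^(−λt) is
effectively linear over the grid, a₀ and β are collinear, and the
"extrapolation" is arbitrary — exactly the situation for an
already-stationary run, where no decay exists to resolve and the mean
fitted plateau (reported as `mean_plateau_a`) is the meaningful estimate.

**RMSD computation.** Unaligned RMSD is evaluated lag-diagonal by
lag-diagonal with a single vectorized kernel; the all-vs-all matrix and
the streaming lag curve (which never materializes the matrix, allowing
~10⁴-frame trajectories in memory) use the same kernel and are
bit-identical. Superposition is the weighted Kabsch solution via
`scipy.spatial.transform.Rotation.align_vectors` (proper rotations only);
degenerate geometries (single atom, coincident centroids) fall back to
the identity rotation, where translation alone is optimal. Default is
superposition on, unweighted atoms; the raw, fit-free distance is
available with `align=False`, mass-weighting via per-atom weights.
Reference-curve ties (most-central / maximum-outlier frame) break to the
smallest frame index.

## The synthetic generator and what it does (not) show

Each of N atoms fluctuates as an independent 3-D Ornstein–Uhlenbeck
process: stationary standard deviation σ per coordinate (Å), relaxation
time τ_c (ps), advanced with the exact discrete update
x_{k+1} = ρx_k + σ√(1−ρ²)ξ, ρ = e^(−Δt/τ_c), so there is no integrator
bias at any frame spacing. Without superposition and for large N,

    RMSD̄(Δt) → √(6σ²(1 − e^(−Δt/τ_c))),   plateau √6·σ,

which serves as the pipeline's closed-form anchor (superposition is
disabled in oracle comparisons because alignment alters the closed form;
aligned behavior is covered by invariance properties instead). Two
departures from stationarity are available: `init_displacement` starts
every coordinate at ±d (transient relaxing with τ_c), and
`drift_velocity` adds a uniform linear drift along x (RMSD̄ then grows
without bound — the signature of a run that cannot converge).

Study conditions used by the acceptance checks, chosen from the scale
analysis above:

- *Stationary anchor*: N = 500, σ = 1, τ_c = 100 ps, Δt = 1 ps, 2·10⁴
  frames → max lag 100 τ_c; the lag curve must match the closed form
  within 2 % at every lag and the fitted plateau fall within 5 % of √6.
- *Transient sweep*: N = 300, d = 5σ, τ_c = 100 ps, 4000 frames, 41
  offsets, fixed schedule with dense head to 4 τ_c. The geometry keeps
  max lag = 10 τ_c at every offset (plateau bias ≈ 3–4 %, constant
  across offsets) while the offset spacing of τ_c/2 resolves the
  transient, whose contribution to the squared plateau decays with time
  constant τ_c/2. Expected pattern: `a` and `τ` strictly decreasing over
  the first offsets, `γ` comparatively constant, extrapolated a₀ within
  10 % of √6·σ.
- *Verdict scenarios*: stationary (τ_c = 100 ps, 5000 frames), transient-
  dominated (τ_c = 2000 ps comparable to the run length, d = 5σ),
  drifting (0.005 Å/frame, i.e. total drift ≈ 10× the plateau), and an
  all-frames-identical run for the `indeterminate` path.

What passing these tests does *not* show: real proteins have correlated,
multi-timescale, anisotropic fluctuations, alignment-relevant global
motions, and no single τ_c; the single-timescale OU model is the simplest
process with the right saturation shape, not a protein model. The tests
validate the estimator machinery and its failure modes, not force fields.

## Numerical conventions and degenerate inputs

- Times in ps, lengths in the input's unit (Å by default); a unit tag
  travels with every container, since RMSD output inherits it.
- Uniform frame spacing is required for index-lag mapping; deviations
  beyond 1e-6 relative from the median spacing raise.
- RMSD matrices must be symmetric within 1e-9 relative (construction) or
  1e-6 (file ingest, symmetrized by averaging), nonnegative, zero
  diagonal.
- Tables are written with 17 significant digits so re-reading reproduces
  every float bit-exactly; the multi-frame XYZ writer does the same,
  giving a bit-exact trajectory round trip (PDB is limited to its fixed
  8.3 coordinate columns).
- t_offset beyond half the trajectory raises (mirroring the offset
  interval of the sweep); a window with fewer than 4 frames raises.
- All stochastic components consume a `numpy` Generator seed; equal seeds
  give bit-identical trajectories and therefore bit-identical pipeline
  outputs.

## Known limitations

- The Hill plateau bias on short windows (see above) is reported, not
  corrected; quantitative a₀ values need max lag ≳ 10 τ_c.
- τ(t_offset) and γ(t_offset) are reported but only a(t_offset) is
  modeled with the exponential decay — the decay model's scope ends
  there.
- No block averaging, no Voronoi/state-space decomposition, no automatic
  truncation-point recommendation: the verdict says whether the analyzed
  window looks stationary, the tables show since when; discarding is the
  user's decision.
- Binary trajectory formats (XTC/DCD) are out of the core contract;
  convert to multi-model PDB/XYZ or ingest a precomputed RMSD matrix.
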