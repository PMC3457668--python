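# lagrmsd

Convergence diagnostics for molecular-dynamics trajectories based on
**lagged RMSD analysis**: a tool to judge when a simulation has *not* yet
run long enough.

A single RMSD-versus-time curve against one reference structure is noisy
and reference-dependent. Instead, `lagrmsd` considers the RMSD between
*pairs* of configurations separated by a fixed time lag Δt, averaged over
all such pairs in the trajectory:

    RMSD(a, b) = [ (1/N) Σᵢ ‖xᵢ(b) − xᵢ(a)‖² ]^½          (configurational distance)

As Δt grows, configurations decorrelate and the mean curve RMSD̄(Δt)
saturates toward the distance between unrelated configurations. The
saturation is modeled with the Hill equation

    RMSD̄(Δt) = a · Δtᵞ / (τᵞ + Δtᵞ)

where `a` is the plateau, `τ` the half-saturation lag (RMSD̄(τ) = a/2) and
`γ` the sigmoidicity. Because the start of a run is biased by its initial
structure, the analysis is repeated while discarding a growing offset
t_offset ∈ [0, t_max/2] from the start; the fitted plateau then follows

    a(t_offset) = a₀ + β · exp(−λ · t_offset)

whose intercept **a₀ extrapolates to the RMSD between totally unrelated
configurations**, free of initial-phase effects. If the fitted parameters
keep changing with t_offset, the trajectory is not stationary yet — the
run is too short. The package turns this into an explicit verdict
(`stationary` / `not_stationary` / `indeterminate`) with reported metrics
and thresholds.

## What's in the box

| module | contents |
| --- | --- |
| `lagrmsd.trajectory` | `Trajectory` and `RMSDMatrix` containers with validated invariants |
| `lagrmsd.io` | multi-model PDB / multi-frame XYZ readers & writers, plain-text RMSD matrices, TSV/JSON tables |
| `lagrmsd.rmsd` | pairwise RMSD, weighted Kabsch superposition, all-vs-all matrix, reference-configuration curves |
| `lagrmsd.lags` | dense-then-geometric lag schedules, lagged mean-RMSD curves (streaming or from a matrix) |
| `lagrmsd.fitting` | Hill and offset-decay least-squares fits with asymptotic standard errors |
| `lagrmsd.sweep` | offset sweep, plateau extrapolation, stationarity verdict |
| `lagrmsd.synthetic` | exact-discretization Ornstein–Uhlenbeck trajectory generator with closed-form lagged-RMSD oracle |
| `lagrmsd.cli` | `lagrmsd simulate / matrix / analyze / sweep` |

## Worked example

Simulate a 4 ns, 100-atom fluctuating system (σ = 1 Å, relaxation time
τ_c = 100 ps) that starts 5σ away from equilibrium, then analyze it:

```sh
lagrmsd simulate --out equil.xyz --n-atoms 100 --sigma 1.0 --tau-c 100 \
    --n-frames 4000 --seed 3 --init-displacement 5.0
lagrmsd analyze --input equil.xyz --frame-spacing-ps 1.0 --no-align \
    --n-offsets 21 --dense-upto 400 --dense-step 20 --sparse-count 30 \
    --schedule-mode fixed --out-dir out
```

prints

```
verdict: stationary
extrapolated plateau a0 = 2.50484 (se 0.001)
```

and `out/offset_fits.tsv` begins (columns abridged)

```
t_offset_ps     a        tau      gamma
0               2.6711   33.859   0.884
200             2.5475   31.705   0.904
400             2.5208   31.151   0.910
```

Reading: at t_offset = 0 the equilibration transient inflates the fitted
plateau (2.67 Å) and slows the apparent saturation (τ ≈ 34 ps); by
t_offset ≈ 400 ps both have settled, the tail of the sweep is flat within
the 5 % tolerance (`verdict: stationary`), and the extrapolated a₀ =
2.505 Å is close to the theoretical unrelated-configuration distance for
this synthetic model, √6·σ ≈ 2.449 Å (the ~2 % excess is the documented
Hill-fit plateau bias; see `docs/methods.md`). For a run that is too
short, the tail never flattens and the verdict is `not_stationary`.

`out/` also contains `lag_curves.tsv` (one RMSD̄(Δt) curve per offset),
`decay_fit.json`, `summary.json` and, with `--plot`, figures of the
curves and parameter trends.

A precomputed RMSD matrix (e.g. from an external engine) can enter
mid-pipeline: `lagrmsd sweep --input matrix.tsv --frame-spacing-ps 3.0 ...`.

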