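# ionpull

A toolkit for **step-wise pulling** analysis: free-energy profiles from
per-step work distributions (Jarzynski and quasi-equilibrium estimators),
stable-state and transition-probability analysis from bias-force
distributions, and single-carrier conductance estimation from work and
displacement statistics. A built-in 1D overdamped Langevin engine provides
a synthetic stand-in for molecular-dynamics trajectories, so every
estimator is testable against analytic ground truth.

## What it does

- **`ionpull.toysim`** — 1D Euler–Maruyama Langevin engine over
  configurable potentials (harmonic, double-well, Gaussian multiwell,
  tabulated), with a stability guard, seed determinism, and two documented
  multiwell "species" fixtures (`K_like`, `Na_like`).
- **`ionpull.protocol`** — the step-wise pulling protocol: a harmonic bias
  `U(z, λ) = k(z−λ)²/2` advanced along a λ ladder (default 25 steps of
  1 Å, τ₁ = 0.5 ns burn-in, τ₂ = 10 ns production, k = 0.6 kcal/mol/Å²)
  with sequential seeding; records per-step positions, distributions
  g_i(z), and work increments `w_i(z) = (k/2)[Δλ² − 2Δλ(z−λ_i)]`.
- **`ionpull.free_energy`** — assembles cumulative work distributions
  (Monte-Carlo or exhaustive product enumeration) and estimates
  ΔF(λ) via the Jarzynski exponential average (log-sum-exp, bootstrap
  SE), the stepwise free-energy-perturbation form, and a mean-force
  (thermodynamic-integration) cross-check; ΔΔF between species,
  selectivity ratios `exp(ΔΔF/kBT)`, and convergence traces vs
  relaxation time.
- **`ionpull.states`** — pooled position histograms (0.01 Å bins),
  univariate Gaussian-mixture decomposition (EM + BIC), force
  partitioning by component 95 % CIs, the three-case transition
  probability rule, spontaneous-jump (negative-force) fractions, and
  detailed-balance overlap diagnostics.
- **`ionpull.conductance`** — pairwise conductance
  `G = (q/L)² ⟨Δz²/Δt_eff⟩ / ⟨W⟩` in pS, its steady-flow inversion,
  dispersion/diffusion terms, and series-resistor totals (negative
  per-pair G allowed; a non-positive total with positive total work
  raises).
- **`ionpull.geometry`** — coordination counting within a cutoff and
  axial-dispersion histograms with a bimodality flag, on tabulated
  (frame, label, x, y, z) coordinates.
- **`ionpull.units`** — the single source of constants
  (kcal/mol, Å, ns, K, e) with explicit SI converters for conductance.

## CLI

```bash
# write a default species-fixture config, then simulate
ionpull fixtures --species K_like --out k.yaml
ionpull simulate --config k.yaml --out runs/k

# analyses
ionpull free-energy runs/k --out k_fe.tsv
ionpull states runs/k --out k_states.tsv
ionpull conductance runs/k --out k_g.tsv
ionpull convergence runs/k --lambda 11 --out k_conv.tsv

# two-species comparison (ΔΔF, selectivity ratio, summary.json)
ionpull analyze runs/k runs/na --out report --conductance
```

Archives are plain-text directories (`run.json` + per-step TSV sample
files); outputs are TSV tables with JSON sidecars carrying the producing
config hash. Exit codes: 0 ok, 1 user error, 2 internal inconsistency.

## Notes on the synthetic engine

The species fixtures are qualitative emulations with documented defaults
(well positions from the target site geometry; depths chosen so the
`Na_like` entry barrier exceeds the `K_like` one by ~3.5 kcal/mol); they
are not fits to any particular channel. Simulation-derived quantities
(ΔF/ΔΔF magnitudes, conductance values) therefore carry toy-scale numbers
with the correct structure, not literal reference values.
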