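# Methods

## Scope and model chain

`prodep` implements the theory chain linking dielectric dispersion spectra
of protein solutions to predicted dielectrophoretic (DEP) response. The
chain has four layers, each usable on its own:

1. a spectrum layer (multi-mode Debye relaxation and effective-medium
   mixtures),
2. the macroscopic boundary-value DEP theory (Clausius–Mossotti factor,
   spheroid depolarization, Brownian thresholds),
3. classical molecular dielectrics (cavity fields, Langevin orientation,
   Onsager reaction field, Kirkwood correlation, Kirkwood–Fröhlich and
   Fröhlich fluctuation relations, protein β-dispersion/dipole links),
4. the two protein-DEP predictors: the empirical `(κ+2)[CM]` factor and the
   dipole-cross-correlation K-factor theory.

## Conventions

- Complex permittivity: `ε* = ε′ − jε″` with the Maxwell–Wagner conduction
  term `ε* = ε − jσ/(ωε₀)`. A single Debye mode is `Δε/(1 + jωτ)`; its loss
  peaks at `ωτ = 1` with height `Δε/2`.
- User-facing frequencies are in Hz; a mode's characteristic frequency is
  `1/(2πτ)`, the mid-point of the dispersion step.
- Dipole moments cross interfaces in debye, fixed at
  1 D = 3.335641×10⁻³⁰ C·m; mean-square moments in fluctuation relations are
  in SI, since that is what an MD trajectory yields.
- Default temperature 295 K (room-temperature DEP experiments); the
  relations calibrated against 25 °C spectroscopy (Oncley, South–Grant)
  default to 298 K. Every function takes an `Environment` override.
- Default solvent permittivity 78.4 (pure water at 25 °C); computations
  tied to published mixture numbers use 78 where those numbers demand it.

## Dispersion fitting

`DebyeRelaxationModel` estimates `(ε_hf, {Δε_i, τ_i})` by bounded nonlinear
least squares (`scipy.optimize.least_squares`, trust-region reflective):

- **Initialization.** Mode positions are seeded at the `n` largest local
  maxima of `−dε′/d(log f)`; amplitudes split the total permittivity drop
  proportionally to peak heights; `ε_hf` starts at the highest-frequency
  sample.
- **Multi-start.** Eight starts with seeded jitter (2% on `ε_hf`,
  log-normal on amplitudes, ±0.4 decades on `log τ`); the best converged
  cost wins. Failure of every start is reported explicitly
  (`DebyeFitResult.success = False`), never silently.
- **Constraints.** `Δε ≥ 0`, `ε_hf ≥ 1` (physicality), and `log₁₀ τ`
  confined to one decade beyond the measured frequency window — outside it
  a mode is not identifiable and degenerates with the baseline.
- **Objective.** Real part only when no loss data are present; equally
  weighted real+imaginary concatenation otherwise. Loss data matter: a
  small δ-type mode (Δε ≈ 2) riding on 1% multiplicative noise of a ~90
  permittivity baseline is at the noise floor in ε′ alone but well resolved
  in ε″.
- **Post-processing.** Modes whose relaxation times agree within 1% are
  merged (strengths summed); output is sorted by increasing characteristic
  frequency.

Measured recovery under the package's own generator (50 log-spaced points,
1% multiplicative noise): median parameter error well under 5% for a
single-mode spectrum over 20 seeds; a two-mode β+δ pair needs loss data for
the small mode at 10% tolerance.

## Spheroid susceptibility conventions

Two conventions for the spheroid DEP susceptibility circulate in the DEP
literature and are *not* mutually consistent at the sphere point. The
factor used with the depolarization presets A = 0.2 (prolate) and A = 0.8
(oblate),

    f_A = (ε_p − ε_m)/(ε_m + A(ε_p − ε_m)),

equals `3·[CM]` at A = 1/3, i.e. three times the moment-normalized sphere
factor. The published Brownian-threshold curves for protein-shaped
spheroids (e.g. ∇E²_th ≈ 6.6×10¹³ V²/m³ for a 3 nm prolate particle with
ε_p = 25 in water at 295 K) are computed with `f_A` as printed, so
`chi_dep` uses `[CM]` for spheres and `f_A` for any other A, and documents
the ×3 seam rather than hiding it. `interface_moment_spheroid` is the
moment-consistent form and reduces exactly to the sphere expression at
A = 1/3.

## Sign of the empirical DEP force

The empirical force relation scales with the dispersed mixture permittivity
`ε_m(f)` and is therefore positive at every frequency if read literally.
The physically meaningful polarity criterion is the dielectric
increment/decrement: positive DEP while `ε_m(f)` exceeds the solvent
permittivity, negative beyond the crossover `f_xo`. `dep_force_empirical`
returns the literal magnitude with that sign attached, so its sign flip
coincides exactly with `crossover_frequency`.

## Kirkwood estimators

`kirkwood_g` implements `g_k = ⟨M²⟩/(Nm²)` for a single configuration
(N, 3) or averaged over a trajectory (T, N, 3). A single configuration of
uncorrelated dipoles has O(1) estimator variance, so sampling-band tests
only make sense on trajectories. The prescribed-correlation oracle uses the
central-dipole estimator `⟨m₀·M⟩/m² = 1 + z⟨cos θ⟩`, for which the
synthetic generator places z neighbours at exact projection `cos θ` around
a random central direction — making the expectation exact by construction
and the Monte-Carlo band purely a check of the isotropic case.

The tetrahedral-network formula is implemented as
`g_k = 1 + z·cos²(θ/2)` (free rotation about H-bonds, no bond bending).
The typographically plausible alternative `1 + z·cos(2θ)/2` is rejected
because it cannot yield the observed `g_k > 1` enhancement at tetrahedral
angles. The X-ray-informed water value `g_k = 2.67` (giving ε = 78.2) is
shipped as a preset, not reproduced ab initio: doing so requires
coordination data and `ε_∞` conventions beyond this package's scope.

## South–Grant static mixture vs. dispersion-amplitude relations

Linearizing the static mixture relation
`ε_mix − ε_sw = S·3ε_mix/(2ε_mix + ε_sw)` about `ε_mix = ε_sw` gives slope
exactly 1 in `S = N_p g_kp m_p²/(3kTε₀V)` — i.e. an effective `h = 1/3` in
the `Δε(β) = h·N g_kp m_p²/(ε₀kT)` notation. The canonical `h = 1/2`
(point-dipole solvent) and `h = 3/4` (continuum solvent) arise from the
dynamic derivation of the dispersion amplitude, not from the static
relation, so the package tests the static linearization against its own
exact first-order result and keeps `h` a free parameter of
`south_grant_delta_eps`.

## K-factor implementation

Only the dilute-limit operative form `K(ω) = (2/9) ε(ω) Δε(ω)/ν_p` is
implemented; the bracketed finite-concentration correction multiplying it
is close to unity in the regimes of interest and its general-α algebra is
anchored instead through enforced limits: α ∈ {0, 1} endpoints of the
cavity susceptibility (Lorentz and vacuum-referenced Maxwell), `χ_c = 1 ⇒
Δε(δ) = 0`, and `N_dip = 0 ⇒ K ≡ [CM]_macro` (the routing function
`dep_susceptibility` enforces the fallback, verified to machine precision
against the macroscopic route). `Δε(ω)` is complexified per mode as
`Δε/(1 + jωτ)` and the real part is taken only at the `χ_DEP` stage.

## Synthetic data

The spectrum generator evaluates the exact complex Debye model on a
log-spaced grid and applies *multiplicative* Gaussian noise to ε′ (and ε″
when requested) — instrument noise in dielectric spectroscopy is
scale-proportional, and tolerance claims in the tests are stated against
this model. Defaults (50 points, 1 kHz–1 GHz, 1% noise in recovery tests)
mirror the sampling of published protein β-dispersion measurements. What
the generator does **not** emulate: electrode polarization, α-dispersion
(double-layer) tails, Cole–Cole broadening, and temperature drift — so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to those real-data artefacts.

The dipole-pair generator draws per-component bivariate Gaussians with a
third of the requested total variance/covariance per Cartesian axis, making
`1 + cov/var` the exact expectation of the cross-correlation estimator.

All generators take explicit integer seeds and share no global RNG state.

## Numerical choices

- Quadratic solves (Kirkwood–Fröhlich, Fröhlich self-consistent,
  South–Grant mixture) use the closed-form positive root; each is strictly
  increasing in its source term and equals the degenerate limit (ε = 1 or
  ε = ε_sw) at zero strength.
- `crossover_frequency` brackets on a 400-point log grid over
  10⁻²–10¹³ Hz and polishes with Brent's method (`xtol = 10⁻¹²` in
  log-space); the dispersion model is monotone non-increasing so the root
  is unique. Agreement with a 10⁵-point brute-force scan is verified to
  within one grid cell over randomized models.
- The Langevin function switches to its series `x/3 − x³/45` below
  |x| < 10⁻⁴ to avoid catastrophic cancellation.
- The general-ellipsoid depolarization integral maps `s = a²t/(1−t)` onto
  [0, 1) and uses adaptive quadrature; the three axis factors sum to 1 to
  ~10⁻⁷.

## Problem sizes

Tests and the acceptance battery are desk-scale by design: the CM-bound
sweep uses ~1.5×10⁶ grid+random points (seconds), fit-recovery runs 20
seeded spectra of 50 points each, and Monte-Carlo estimator checks use
10⁴–10⁵ samples with 3σ sampling bands. The whole suite completes in well
under a minute on one CPU.

## Known limitations

- No Cole–Cole / Havriliak–Negami broadening, electrode-polarization
  correction, or Kramers–Kronig machinery; spectra below ~1 kHz are outside
  the validity of every model here (double layers and conduction dominate),
  and `cm_factor` warns accordingly.
- Spheroid formulas assume field-aligned axes; no orientational averaging
  for tumbling spheroids is attempted.
- Electrode geometry is out of scope: `∇E²` is always an input.
- The empirical `(κ+2)[CM]` scale depends on the mole-volume-fraction
  concentration convention; published magnitudes (~10³–10⁴ for common
  proteins) are shipped as provenance notes, not asserted values, because
  their inputs live in the primary experimental literature.
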