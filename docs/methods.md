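# Methods

## The model

`burstkit` simulates a single auto-repressive gene with transcriptional
bursting. The promoter is a two-state telegraph process: it switches
ON → OFF at rate λ(P/P₀)ʰ (repression by the gene's own protein, with
threshold P₀ and Hill coefficient h) and OFF → ON at the constant rate λ.
While ON, transcription initiates at rate α_M, and each initiated mRNA
enters the system a fixed delay τ later, representing transcription plus
nuclear export; initiated transcripts are delivered regardless of later
promoter switching, because production is tied to the promoter state at
the moment of initiation. mRNA is translated at rate α_P per transcript,
and both species decay with first-order rates μ_M and μ_P.

Parametrizing both switching directions with the same timescale λ keeps
the stationary ON probability equal to the Hill function
f(P) = 1/(1 + (P/P₀)ʰ) independently of λ, so varying λ changes only the
*timescale* of bursting, never the mean transcription rate. Two global
scales then isolate the two noise sources:

- **system size Ω** — molecule counts at fixed concentration scale with Ω,
  so copy-number noise scales as Ω^(−1/2);
- **bursting parameter λ** — promoter-switching noise scales as λ^(−1/2).

Setting either scale to infinity removes that noise source exactly, giving
four tiers:

| tier | Ω | λ | module |
|---|---|---|---|
| full delayed SSA | finite | finite | `ssa_delay.simulate_full` |
| piecewise-deterministic process | ∞ | finite | `pdmp.simulate_pdmp` |
| copy-number-noise-only SSA | finite | ∞ | `ssa_delay.simulate_full` |
| deterministic delay ODE | ∞ | ∞ | `core_models.integrate_dde` |

Between the discrete tiers and the ODE sit the diffusion approximations in
`cle`: the **extended chemical Langevin equation**, whose mRNA noise
carries an extra bursting variance

σ²_burst(P) = (α_M²/λ) · 2(P/P₀)ʰ / (1 + (P/P₀)ʰ)³,

added to the classical copy-number variance (α_M f(P) + μ_M M)/Ω, and the
**linear-noise approximation (LNA)**, the linearization about the
deterministic fixed point (M*, P*) with amplitudes frozen there. The LNA
admits closed-form two-sided spectra S_M(ω), S_P(ω) (`lna_spectra`) whose
integral (1/2π)∫S dω equals the stationary variance.

A delay-free two-gene **toggle switch** with mutually repressive telegraph
promoters exercises the same machinery on a bistable motif
(`simulate_toggle_ssa`, `simulate_toggle_cle`, `toggle_fixed_points`).

### A note on the mRNA drift

The mRNA drift of the extended CLE is implemented as
α_M·f(P(t−τ)) − μ_M·M, consistent with the deterministic limit and with
the α_M² scale of the bursting variance. A variant without the α_M factor
is reachable through `simulate_cle(..., drift_alpha_m=False)` for
comparison purposes; it is not the default because its λ→∞, Ω→∞ limit does
not reduce to the delay ODE.

## Reference parameters

`REFERENCE_PARAMS` is the experimentally derived rate set for an ultradian
(Hes1-type) oscillator in mouse neural progenitor cells:
α_M = 39.93 cu·min⁻¹, α_P = 21.56 min⁻¹, μ_M = ln2/30 min⁻¹,
μ_P = ln2/90 min⁻¹, h = 4.78, P₀ = 24 201.01 cu, τ = 33 min.
Concentrations are in "cu" — one molecule per reference nuclear volume
V₀ = 523 fL, so Ω = 1 means P* ≈ 6.0 × 10⁴ protein molecules per nucleus.
With these rates the deterministic ODE spirals into a stable fixed point;
all sustained oscillations in the stochastic tiers are noise-induced.

## Numerical choices

- **Delayed SSA.** Delay handled as a scheduled-event queue (constant τ
  keeps it FIFO); when the earliest arrival precedes the next tentative
  reaction, time advances to the arrival and the exponential clock is
  redrawn, which is exact by memorylessness. Sampling onto the output grid
  is zero-order hold, since the true state is piecewise constant. The
  initial promoter state is drawn Bernoulli(f(P_init)) — the stationary
  conditional law — to minimize equilibration bias; `init="fixed-point"`
  rounds Ω·(M*, P*) to counts.
- **PDMP.** Heun steps (default dt = min(sample_dt, 0.01) min) between
  switches; the ON→OFF hazard ∫λ(P/P₀)ʰ ds is accumulated by the trapezoid
  rule on the same grid and the crossing time refined by linear
  interpolation within the step, keeping the jump-time error O(dt²).
  Hazard inversion was chosen over thinning because P has no a-priori
  bound during transients. The delayed drive σ(t−τ) is looked up in the
  recorded switch history. The hazard is evaluated in log space so large
  P/P₀ with large h cannot overflow.
- **CLE / LNA.** Euler–Maruyama with independent per-channel normal
  increments (the mRNA and protein noises are uncorrelated because no
  reaction changes both species). The delayed protein value is read from a
  ring buffer at lag round(τ/dt); τ is snapped to the grid, as in the
  deterministic integrator, so the zero-noise limit is step-comparable
  with the ODE solution. States (and the variance arguments) are clamped
  at zero — simple, and far from the boundary in the approximation's
  validity regime; LNA fluctuations are not clamped. Default dt = 0.01 min;
  the long toggle runs use dt = 1 min.
- **Fixed points.** Bisection on the bracketed monotone equation
  P(1 + (P/P₀)ʰ) = α_Mα_P/(μ_Mμ_P), driven to machine resolution
  (residual ≲ 10⁻¹¹ relative). Toggle fixed points come from a sign-change
  scan of the scalar composition map A ↦ (α/μ)f((α/μ)f(A)) on [0, α/μ]
  refined by Brent's method; the result is symmetric under A↔B by
  construction of the scan.
- **Spectral variance.** Σ² = (1/2π)∫S dω is integrated piecewise over one
  delay period 2π/τ at a time (the integrand oscillates through cos ωτ),
  then extended octave by octave with the analytic tail
  σ²/ω_max + c/(3ω_max³) until the result is stable to 10⁻⁹ relative.
- **Periodogram.** Rectangular window, per-trajectory mean subtraction,
  normalization S_k = Δt|X_k|²/N, which makes the discrete Parseval
  identity (1/2π)ΣS Δω = sample variance hold exactly for every input.
- **Σ estimator.** Ensembles are pooled with one global mean (sums and
  sums of squares accumulated across trajectories); this is a documented
  convention, chosen over averaging per-trajectory Σ values.
- **Waiting times.** Centered moving average (default 1000 min), dwell =
  a maximal run with the high channel above and the low channel below the
  4 cu threshold; runs touching either series end are discarded as
  censored, which is unbiased for the mean under stationarity.
- **Seeds.** Every simulator takes one integer seed; sweeps derive
  per-cell, per-replicate streams with `numpy.random.SeedSequence`
  counter-based splitting, so cells are reproducible independently and in
  parallel. Identical seeds give bit-identical trajectories.

## Deterministic history and initial conditions

The ODE/SDE integrators default to zero pre-history (M, P ≡ 0 for
t ≤ 0) where an initial state is not given; stationary analyses start at
the fixed point and discard an equilibration window (200 min for spectra,
2000 min for the accuracy survey), which removes sensitivity to the
choice. These are conventions, not inferences.

## Problem sizes in tests and the acceptance script

The accuracy survey protocol is: trajectories of T = 10⁵ min, first
2000 min discarded, 2 trajectories for λ ≤ 0.1 min⁻¹ and 20 otherwise.
`scripts/acceptance.py` runs that protocol unchanged for the two reported
cells (Ω = 1 at λ = 0.1 and λ = 1). The test suite reruns the same
comparisons at reduced problem sizes chosen to keep the default run
desk-scale — T = 10⁴ min × 20 trajectories for the in-region CLE check,
T = 4 × 10³ min with small ensembles for the Ω = 100 cells, and T = 10⁶
min (down from 10⁷) for the toggle moments and waiting times — and widens
each stochastic assertion by a percentile bootstrap over trajectories
(block bootstrap for single long runs), never below five points on a
percentage quantity.

## What the tests do and do not show

All test data are generated by the simulators themselves; there is no
external data. The oracle tests (Poisson stationary law, matrix
exponential between switches, Lyapunov covariance for the memoryless
cascade, discrete Parseval) check exactness of the discrete simulators
and estimator conventions against independent closed forms. The
quantitative reproductions check that the tiers agree — and disagree — in
the documented (λ, Ω) regimes at bootstrap resolution. None of this
validates the biological model itself: real promoters need not be
two-state, delays are not sharp constants, and parameters are taken as
given rather than inferred.

## Known limitations

- The CLE requires both Ω and λ large; at slow bursting (λ ≲ 0.1 min⁻¹)
  increments are visibly non-Gaussian and the relative error of Σ_P
  reaches tens of percent. The package reports this breakdown rather than
  papering over it.
- No tau-leaping or hybrid acceleration: the full SSA at large Ω is slow
  by design (it is the reference tier, not the workhorse).
- One promoter copy per gene; multi-allele extensions would need extra
  promoter states.
- PDMP support covers the feedback motif only; the toggle switch is
  simulated as SSA and CLE.
- Spectra are available at stable fixed points only; no spectral theory
  for the bistable toggle.
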