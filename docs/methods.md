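# Methods

## Model and assumptions

The package implements a three-compartment stochastic delay system for
susceptible (S), vaccinated-in-process (V) and infected (I) densities.
Recruitment and natural death share one rate μ, so total mass is
conserved in expectation; the recovered compartment decouples from the
(S, V, I) dynamics and is not simulated.  Temporary immunity enters as
delayed return flows γ₁e^{−μτ₁}I(t−τ₁) (post-infection) and
γ₂e^{−μτ₂}V(t−τ₂) (post-vaccination); the exponential factors are the
survival probabilities over the immunity periods.  Incidence is the
four-parameter saturated (Hattaf-type) form, bounded above by the
bilinear rate βXI because its denominator is ≥ 1 for nonnegative states —
a fact the code asserts rather than guards, since no nonnegative state
can make the denominator vanish.  Each compartment carries independent
multiplicative white noise.

Vaccinees are assumed less susceptible than the unvaccinated (β₂ < β₁).
Violating this is biologically odd but mathematically harmless, so the
validator warns and proceeds.

## Threshold quantities

All thresholds are closed-form in the parameters.  The composite rates

    cᵢ = (γᵢ(1 − e^{−μτᵢ}) + μ)(α + μ),  i ∈ {1, 2}

combine loss of immunity with mortality.  The stochastic reproduction
number R₀ˢ has two transmission terms sharing the noise-shifted
denominator γ₁ + μ + σ₃²/2; the second term's saturation denominator is
η₁αμ + c₂.  **Choice of c₂:** one printed statement of the formula has c₁
in that position, but every numerical threshold value the reference
experiments report (0.9561, 1.0177, 1.0994, 1.2396, 0.8553, 1.2402) is
reproduced only with c₂, which is also the constant appearing at that
position throughout the derivation (it is c₂ that defines the
disease-free V-coordinate αμ/c₂ the linearisation expands around).  The
implementation therefore uses c₂ and treats the lone c₁ as a typo.

**Two L₂ variants.**  The persistence threshold I* divides
(γ₁+μ+σ₃²/2)(R₀ˢ−1) by L₁ + L₂.  The closed form of L₂ stated alongside
the persistence theorem gives I* ≈ 0.0761 for the supercritical preset,
while the coefficient β₂c₁/(η₁αμ+c₂) that appears one step earlier in the
same derivation gives I* ≈ 0.1246, matching the reported 0.125 and the
downstream S* = 0.0898.  The discrepancy is in the source analysis, not
in this implementation, so both variants are exposed:
`mode="paper_figures"` (default, the derivation coefficient) and
`mode="theorem"` (the stated closed form).

**Reporting precision.**  `reported_thresholds` reproduces the reference
rounding cascade: I* to 3 decimals, S* from the unrounded I* to 4
decimals, and V* computed from the *rounded* I* and S* before its own
4-decimal rounding (the unrounded V* is 0.2171; the cascade gives the
reported 0.2168).  Internal computation always uses full precision.

## Integrators

Both schemes run on uniform grids where T/h, τ₁/h and τ₂/h are integers
(relative tolerance 1e-9); non-commensurate grids are rejected rather
than rounded, because the split-step delay interpolation
θx_{n−m+1} + (1−θ)x_{n−m} is only defined for integer delay offsets m.
Only point initial values are specified by the reference experiments, so
the default history is the constant extension of (S₀, V₀, I₀); arbitrary
positive history functions are supported.  History values must be
strictly positive (the well-posedness assumption); an `allow_zero` escape
admits exact zeros for boundary studies such as the disease-free axis.

Brownian increments are ΔW = √h·ξ with ξ standard normal.  (A printed
form without the square root would make the increment variance h² and
the Milstein correction dimensionally wrong; the √h scaling is the one
under which both schemes are consistent.)  Increments are drawn
(ΔW₁, ΔW₂, ΔW₃) per step in a fixed order from `numpy`'s PCG64 generator,
so the two schemes can be driven by identical noise for coupled
comparisons, and identical (parameters, grid, history, seed, method)
yield bit-identical trajectories.  Ensemble path k derives its seed
deterministically from (base_seed, k) via `SeedSequence`.

The SSTM update is explicit with the Milstein correction
(σ²/2)X(ΔW²−h) applied per equation with that equation's own σ and ΔW
(diagonal noise, no cross terms).  The SSSTNSFD update replaces h by
v(h) = 1 − e^{−h} and moves every loss term into the denominator; with
zero noise each numerator and denominator is positive, so positivity
holds for arbitrary h.  With noise, the I-update numerator contains
1 + σ₃ΔW₃ and can go negative when σ₃ΔW₃ < −1 — a real possibility under
large σ₃ that no positivity claim for the stochastic scheme survives.
Neither scheme clips: negative iterates are recorded as
(step, component) pairs in `positivity_violations` and propagated, so
scheme failures stay observable.  Non-finite states abort with the step
index and the violations recorded so far.

## Diagnostics

Time averages use trapezoidal quadrature on the trajectory's own grid
(exact for constant and linear paths).  The extinction monitor compares
the realised ln I(T)/T with its almost-sure bound
(γ₁+μ+σ₃²/2)(R₀ˢ−1); the persistence monitor compares ensemble time
averages with (I*, S*, V*).  All asymptotic statements are reported as
horizon-T observations with the horizon printed; no convergence claim is
made.  In particular, the deterministic supercritical run's ⟨I⟩ over
[0, 200] sits within 1% of I* but marginally *below* it — the bound
constrains the limit, not any finite horizon — and the tests assert it
with that slack.

The boundedness envelope for the nonstandard scheme is the recursion
Mₙ = μv(h) + (1 + σΔWₙ)Mₙ₋₁ with σ = max(σ₁, σ₂, σ₃) and ΔWₙ the
componentwise-max increment.  Its starting value T* is read as the sum of
two fractions, μ/(γ₂(1−e^{−μτ₂})+μ) + αμ/c₂ ≈ 0.6208 for the base
parameters (by analogy with the disease-free V-coordinate αμ/c₂); an
override parameter accepts any other reading.  Because the standard
initial mass 0.8 exceeds that T*, the certificate starts from
max(T*, S₀+V₀+I₀) by default so it is usable on the shipped presets; a
strict mode enforces the hypothesis S₀+V₀+I₀ ≤ T* and refuses otherwise.
The recursion's validity requires every factor 1 + σΔWₙ > 0; steps
violating that void the certificate and are listed rather than hidden.

## Presets and study conditions

The six presets share the base set μ=1, α=10, γ₁=1.5, γ₂=2.4, θ=0.5,
τ₁=1, τ₂=2, σ=(0.1, 0.02, 0.05), λ=(0.2, 0.3, 0.4), η=(0.4, 0.2, 0.1),
initial values (0.3, 0.3, 0.2), horizon T=100 and h=0.1 (h=0.5 for
`coarse_step`).  `weak_saturation` *retains* the shortened immunity
periods τ₁=0.8, τ₂=1.3 of `short_immunity`: the experiments are
cumulative, and only that reading reproduces the reported R₀ˢ = 1.0994
(resetting the delays would give ≈ 1.0233).  Stochastic experiments
default to a single path with the seed recorded in the run manifest;
ensemble sizes of 30 paths are used where an ensemble statement is
tested, enough to pin the sign and scale of the ensemble means at these
noise levels while keeping the full suite in seconds.

## What the synthetic conditions do and do not show

The presets exercise the model in well-separated regimes (deep
subcritical, marginal, supercritical, noise-suppressed, coarse-grid).
Passing tests show the schemes reproduce the closed-form theory under
those conditions; they say nothing about fitting real surveillance data,
non-constant history functions estimated from data, parameter regimes
with near-singular saturation, or strong-convergence order, none of
which the package claims.

## Numerical choices

- Grid commensurability tolerance 1e-9 (relative); delays shorter than
  one step are rejected.
- Trajectory CSVs are written with `%.17g`, which round-trips doubles
  exactly and makes reruns byte-identical.
- The coupled-scheme agreement test at h=0.01 over [0, 10] freezes an
  empirical tolerance of 0.05 against a measured maximum gap of ≈ 0.012.
- The positivity sweep at h=5 uses delays (τ₁, τ₂) = (5, 10), since the
  base delays are not commensurate with that step.
- Per-path seeds are reduced mod 2³¹.

## Known limitations

- The stochastic positivity of the nonstandard scheme is an empirical
  observation at the shipped noise levels, not a theorem; violations are
  recorded whenever they occur (they do occur at σ₃ = 1.5).
- The boundedness certificate's validity window shrinks as σ grows; with
  heavy noise many steps void it.
- No adaptive stepping, no general user-supplied SDE systems, no
  strong/weak convergence-order certification.
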