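# Methods

## Model

`qicsim` simulates a transcriptional device with an embedded
post-transcriptional feedback controller. The reduced model has three states —
mRNA co-transcript `m1`, silencing sRNA `s1`, output protein `y1`:

    dm1/dt = T·D·H(u1) − (λ/β)·m1·s1 − δ·m1
    ds1/dt = A(y1)     − (λ/β)·m1·s1 − δ·s1
    dy1/dt = R·(1−d)·m1/κ_GFP − γ·y1

with actuation `A(y1) = k·Ts·y1` (linear) or, optionally,
`Ts·K·(k·y1)/(K + k·y1)` with half-saturation `K` (`actuator_saturation`),
normalised so the linear law is recovered as `K → ∞`. The saturating form
models a sensor promoter that cannot be driven arbitrarily hard; it is off by
default.

Assumptions baked into the reduction:

- The sensor protein is translated from the same transcript as the output at
  `k` times its rate (`k = κ_GFP/κ_ECF32`), both proteins decay at the shared
  rate γ, and the system starts from steady-state gene expression, so
  `p1 = k·y1` identically. The `full` four-state variant keeps `p1` explicit
  and is used to test this reduction rather than to replace it.
- Uncoupled mRNA and sRNA decay share one rate constant δ. Unequal RNA decay
  rates are out of scope.
- The disturbance `d` (fold drop in free-ribosome availability) is exogenous
  and piecewise-constant; no mechanistic ribosome pool is modelled, and
  transcription-level perturbations are not addressed by this architecture.
- λ and β enter only as the effective second-order coupled-decay rate λ/β;
  they are stored separately for interpretability but consumed as a ratio.

The controller structure: subtracting the sRNA balance from the mRNA balance
gives the memory dynamics `dz/dt = k·Ts·e − δ·z` for `z = m1 − s1`,
`e = T·D·H(u1)/(k·Ts) − y1`. With δ = 0 this is an antithetic integrator and
the steady-state output `y1 = T·D·H(u1)/(k·Ts)` is independent of `d`
(perfect adaptation). With δ > 0 the integrator leaks; at equilibrium
`e_ss = δ·z_ss/(k·Ts)`, which the test suite checks at every computed fixed
point. Quasi-integral behaviour requires the three ratios δ/λ, δ/T and
δ/(k·Ts) to be small; `qic_check` reports them with a default threshold of
0.1 — an operational reading of "much less than 1"; raw ratios are always
returned so stricter cutoffs can be applied.

## Parameters and defaults

Units: hours and nM-like arbitrary concentration units. The device library's
rate constants are representative, chosen once from bacterial physiology (the
circuits' fitted constants are not published with the model):

| parameter | default | rationale |
|---|---|---|
| δ | 8 h⁻¹ | ~5-min uncoupled RNA half-life (RNase + dilution) |
| γ | 1.4 h⁻¹ | dilution-dominated protein decay, ~30-min doubling |
| λ, β | 800 h⁻¹, 10 nM | λ/β = 80 nM⁻¹h⁻¹ so coupled decay dominates (δ/λ = 0.01) |
| T | 300 / 100 nM·h⁻¹copy⁻¹ | stronger / weaker constitutive promoter |
| D | 10 | medium-copy plasmid |
| Ts | 20 h⁻¹ | modest sigma-factor-dependent promoter activity |
| κ_GFP | 100 nM | fixed output RBS |
| R | 1000 nM h⁻¹ | maximum translation capacity |

Feedback gains follow the sensor-RBS translation initiation rates 565, 1127
and 6474 against the fixed output RBS TIR of 974, under the convention
TIR ∝ 1/κ with unit proportionality (no published conversion exists; the
convention only fixes the scale of k, and k enters the model solely as the
ratio). This yields k ≈ 0.58 / 1.16 / 6.65 for low / medium / high gain.
Under these defaults only the high-gain devices pass all three QIC conditions
(δ/(k·Ts) = 0.69, 0.35, 0.060), matching the design narrative that robustness
is won by raising the gain.

## Numerics

- **Integration**: `scipy.integrate.solve_ivp` with the BDF stiff method,
  rtol 1e−8 / atol 1e−10. The integrator restarts at every disturbance
  breakpoint, so discontinuities in d are exact and results are
  solver-agnostic; no event detection is used. Output is dense-interpolated
  onto 500 evenly spaced points per disturbance segment (configurable). A
  breakpoint time belongs to the following half-open interval, and the stored
  `d` column respects that convention. Components more negative than a 1e−9
  relative tolerance abort the run; smaller excursions are clipped to zero.
- **Steady states**: the unregulated (`m* = TDH/δ`,
  `y* = R(1−d)TDH/(δγκ_GFP)`) and ideal δ = 0 variants use closed forms. The
  leaky regulated fixed point is reduced to a scalar root: the equilibrium
  translation balance ties `m1 = κ_GFP·γ·y1/(R(1−d))`, and subtracting the RNA
  balances ties `s1` to `y1`, leaving one equation bracketed between zero and
  the unregulated output — solved with `brentq` at 1e−13 relative tolerance.
  The Jacobian at the root is checked for eigenvalues with negative real
  parts; instability raises rather than returning a spurious point. The solver
  is cross-validated against long stiff integration (horizon 50/min(δ, γ))
  on randomized parameter sets.
- **Settling time**: first time after which the output stays within 2% of its
  final value — a standard control-engineering convention, configurable.
- **Memory-law residual**: computed from RHS evaluations (not finite
  differences), scaled by the combined magnitude of the law's opposing terms
  so that equilibrated trajectories (where `dz/dt ≈ 0` by cancellation) are
  scored sensibly.

## Open design choices

- `H(u1)`: the library devices are constitutive (H ≡ 1); Hill activation and
  repression forms are provided for generality since regulated promoters only
  need `H ∈ [0, 1]`.
- Gain sweeps vary κ_ECF32 with κ_GFP fixed, mirroring the experimental
  tuning knob (sensor RBS strength).
- The robustness metric is defined directly on the model's `d`; a separate
  Hill mapping (`competitor_to_disturbance`) converts an inducer dose for a
  resource competitor into `d` when a dose axis is wanted, since the model
  treats competitor activation as exogenous.
- The open-loop silencing experiment drives sRNA transcription from an
  externally induced sensor level `sensor_max·Hill(dose)` (default
  `sensor_max` 300 nM, half-max dose 30, Hill coefficient 2, no basal leak)
  against a constitutive target; no fitted constants are claimed for it.
- Pre-equilibration is the default initial condition for simulations, matching
  the assumption that experiments start from steady-state expression.

## What the simulations do and do not show

All experiments here are simulations of the deterministic model; there is no
biological data in the package. The fixture library emulates the structure of
a real device library — promoter strength, RBS-tuned gains, regulated vs
unregulated variants — but not its absolute expression levels, growth-rate
feedback, gene-expression noise, or plate-reader logistics (batch re-dilution
is not emulated). Passing tests therefore demonstrate properties of the model
and the correctness of this implementation, not quantitative agreement with
any measured circuit.

Known limitations worth noting:

- At very high gain the adaptation error stops falling: with finite λ/β the
  equilibrium sRNA level grows with k and the uncoupled-decay term δ·s1 in
  the mRNA balance leaves a residual error floor ≈ δβ·γ·κ_GFP/(λ·R(1−d))
  relative to a shrinking set point, so robustness peaks and then declines
  very slightly beyond k ≈ 7 under the default parameters. Monotonicity
  properties are therefore asserted over the gain range the library actually
  spans.
- The deterministic model cannot address noise propagation, and the
  post-transcriptional controller cannot reject transcription-level
  perturbations by construction.
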