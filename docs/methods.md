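# Methods

## Model and coordinates

The DC model tracks a diabetic population in two compartments: with
complications `C(t)` and without `D(t)`, total `N(t) = C(t) + D(t)`. The
native two-compartment form is

```
D′ = I − (λ + μ) D + γ C
C′ = I + λ D − θ C            θ = γ + μ + ν + δ
```

with incidence entering both compartments (a share of new diagnoses
already presents with complications). Summing and eliminating `D = N − C`
gives the `(C, N)` system the package treats as ground truth:

```
C′ = I − (λ + θ) C + λ N
N′ = 2I − (ν + δ) C − μ N
```

an affine linear system `x′ = A x + b`. Both forms are implemented
(`rhs`, `rhs_dc`) and their consistency (`D′ + C′ = N′`) is asserted in
tests. All populations are stored as floats; only table writers round.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| λ | complication development rate | 1/yr | 0.85 |
| δ | mortality due to complications | 1/yr | 0.05 |
| μ | natural mortality | 1/yr | 0.02 |
| γ | complication control rate | 1/yr | 0.5 |
| ν | severe-disability rate | 1/yr | 0.05 |
| I | incidence of diabetes | persons/yr | 6×10⁶ |

The defaults are the canonical parameterisation of the analysis; sweeps
explore γ ∈ {0.04, 0.08, 0.5, 1.0}, λ ∈ {0.04, 0.66, 0.85, 1.2},
δ ∈ {0.02, 0.05, 0.1, 0.35}, μ ∈ {0.005, 0.02, 0.45},
ν ∈ {0.03, 0.05, 0.1, 0.35}. λ is nominally a probability; the value 1.2
is accepted as a rate with a logged warning. Validation requires all six
values nonnegative and at least one of μ, δ, ν positive (otherwise the
system has no outflow and no equilibrium).

## Exact solution

Two routes, kept deliberately independent and cross-asserted:

* **Modal closed form** (`analytic_coefficients`, `analytic_C`,
  `analytic_N`): `C(t) = K₁e^(−η₁t) + K₂e^(−η₂t) + (α/β)I` with
  `σ = λ+θ+μ`, `β = λ(ν+δ)+μ(λ+θ)`, `α = 2λ+μ`,
  `η₁,₂ = (σ ∓ √(σ²−4β))/2`. `K₁` follows the standard closed form; `K₂`
  is its η₁↔η₂ mirror, which is what the t=0 constraint
  `K₁+K₂+C_inf = C₀` forces (and what an eigenvector decomposition gives).
  `N(t)` is recovered from the first ODE,
  `N = (C′ + (λ+θ)C − I)/λ`, which guarantees ODE-consistency; it is
  undefined at λ=0, where C decouples and N should be integrated directly.
* **Affine propagator** (`propagate`): the matrix exponential of the
  augmented matrix `[[A, b], [0, 0]]` acting on `(C, N, 1)`. This is exact
  for repeated eigenvalues and singular `A` without case analysis, and is
  the truth oracle for every error table.

For nonnegative rates the discriminant `σ²−4β = (λ+γ+ν+δ)² − 4λ(ν+δ)`
is bounded below by `(λ+s)² − 4λs ≥ 0` with `s = ν+δ` (AM–GM), so the
spectrum is always real: complex modes cannot occur in the physical
parameter region, and the stability classifier's spiral/center branches
are exercised only by synthetic eigenvalue pairs.

## Equilibrium variants

`equilibrium(..., "ode_consistent")` solves `A x = −b` exactly; this is the
state trajectories converge to (`N* ≈ 148.95×10⁶` at defaults) and the
default everywhere. The closed-form critical-point expressions are kept as
`variant="paper_formula"` for transparency; their `C*` agrees
algebraically with the linear solve, while their `N*` (≈150.52×10⁶ at
defaults) is not a root of the ODEs and is never used downstream.

## Numerical schemes

All five schemes are fixed-step by design — step-size effects are the
object of study. Implementation choices where a naive transcription would
be ambiguous or wrong:

* **Implicit Euler**: the componentwise update equations are mutually
  coupled; the step solves `(1 − Δt A) x_{i+1} = x_i + Δt b` exactly. A
  single Gauss–Seidel sweep (C from lagged N, then N from new C) is
  available behind a flag for fidelity experiments.
* **Heun**: explicit-Euler predictor, trapezoidal corrector averaging the
  derivative at the current state and at the predictor.
* **RK4**: classical coefficients — half-step stages 2–3, full-step
  stage 4. Anything else fails to reach the ~10⁻⁷ % errors the scheme is
  known for on this system.
* **ABM4**: Adams–Bashforth 4-step predictor, derivative re-evaluation at
  the predictor, Adams–Moulton corrector (PECE); the first three steps are
  bootstrapped with RK4 and the 4-state window then slides. Derivatives
  are plain right-hand-side values; Δt enters only through the Adams
  weights Δt/24.
* **Divergence guard**: a trajectory is flagged divergent and truncated
  when |C| or |N| exceeds 10¹² persons or becomes non-finite — more than
  10³× the population scale, unreachable by any stable run.

`amplification` reports per-mode growth factors: the scheme's stability
function evaluated at `Δt·η₁` and `Δt·η₂` (`1−x` for explicit Euler,
`1/(1+x)` implicit, `1−x+x²/2` Heun, the quartic polynomial for RK4) and,
for ABM4, the largest-magnitude root of the PECE characteristic
polynomial. Explicit Euler destabilises at `Δt = 2/η₂ ≈ 1.420` yr for the
default parameters, which is why the Δt-sweep's 1.5-yr point is the first
flagged unstable; ABM4's PECE radius already exceeds 1 at Δt = 1, visible
as its slow error growth at that step size.

## Anchoring and the study window

The t=0 initial conditions behind the reference trajectory are not
recoverable (the equilibrium ± 500 recipe leaves the sign unresolved, and
back-propagating the tabulated states does not land on either choice), so
all quantitative comparisons anchor at the tabulated t=5 state
(C = 90,880,136.51, N = 150,047,685.76) and run over [5, 20] years with
reporting at t = 5, 10, 15, 20. A consequence: anchored runs take 15 unit
steps where the original 20-step runs accumulated 5 extra steps of error,
so tabulated reference errors act as upper bounds for the anchored ones.
The fixture ships as a four-row CSV inside the package, and its own
acceptance test is self-consistency: exact propagation of the t=5 row
reproduces the t=10/15/20 rows within ±5 persons (the 2-decimal rounding
of the anchor propagated forward).

## Synthetic parameter generation

`random_stable_parameters(seed, n)` draws rates uniformly from
[10⁻³, 1.5] and incidence log-uniformly from [10⁴, 10⁷] — brackets that
span the canonical values and every swept value while staying in a
demographically plausible range. Every draw is provably an asymptotically
stable node (see the discriminant bound above); draws within a
configurable gap of a repeated root are rejected so the two-mode closed
form always applies. The generator emulates parameter uncertainty only: it
does not emulate age structure, stochastic demography, time-varying
incidence or a prediabetes stage, so passing property tests demonstrate
correctness of the solver/analysis machinery on the model class, not
epidemiological realism of any single draw.

## Numerical choices and tolerances

* Equality of the two exact routes is asserted at 1e-10 relative; the
  brute-force cross-check integrates RK4 at Δt = 10⁻³ over 20 years and
  agrees with the propagator to 1e-8 relative.
* Empirical convergence orders use error ratios under Δt halving
  (0.5→0.25 for the order-1/2 schemes and ABM4, 1.0→0.5 for RK4, whose
  finer-step errors approach the float64 floor of the 9×10⁷-person scale).
* Problem sizes throughout (≤150 steps per trajectory in sweeps, 10³
  random draws in the heaviest property test) keep the whole suite around
  a second; they were chosen as the smallest sizes at which every
  asymptotic claim (orders, monotonicities, stability thresholds) is
  cleanly resolved above roundoff.
* Grid times are matched at 1e-9 relative tolerance; report times must lie
  on the step grid — there is no interpolation anywhere.

## Known limitations

* The model is linear with constant incidence; it cannot saturate, and
  its scenario grid scales exactly linearly in I by construction.
* The two-compartment form counts incidence into both compartments; if
  new diagnoses were complication-free, the N equation would carry `I`
  rather than `2I` and all constants would shift.
* The scenario grid reproduces structure (linearity in incidence,
  monotonicity in λ), not any particular published cell values, which
  depend on unstated horizons and initial conditions.
* ABM4 below four grid points degenerates to its RK4 bootstrap.
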