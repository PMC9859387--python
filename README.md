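# dcmodel

A tested, reusable implementation of the diabetes-complications (DC)
compartmental model: a two-compartment population model of diabetics with
and without complications, together with its exact solution, five classic
fixed-step integration schemes, eigenvalue stability analysis, and the
error/step-size/parameter/scenario studies built on top of them.

It is aimed at epidemiological modellers and numerical-methods students who
want a small, fully transparent linear compartmental system on which exact
answers exist for every question a solver benchmark can ask.

## The model

The diabetic population splits into people with complications `C(t)` and
without, `D(t)`; the total is `N(t) = C(t) + D(t)`. With constant incidence
`I` (new diagnoses per year, entering both compartments), complication
development rate `λ`, control rate `γ`, natural mortality `μ`,
complication mortality `δ` and severe-disability rate `ν`, the dynamics in
`(C, N)` coordinates are the affine linear system

```
C′(t) = I − (λ + θ) C(t) + λ N(t)          θ = γ + μ + ν + δ
N′(t) = 2I − (ν + δ) C(t) − μ N(t)
```

i.e. `x′ = A x + b`. The solution is a sum of two decaying modes,

```
C(t) = K₁ e^(−η₁ t) + K₂ e^(−η₂ t) + (α/β) I
```

where `−η₁, −η₂` are the eigenvalues of `A` (`η₁η₂ = β = det A`,
`η₁ + η₂ = σ = −tr A`, `α = 2λ + μ`), and `(α/β) I` is the equilibrium
prevalence of complications `C*`. For any nonnegative rates the spectrum is
real and negative, so the equilibrium is an asymptotically stable node.

Five fixed-step schemes are implemented from scratch against this system —
explicit Euler, implicit Euler (exact 2×2 solve per step), Heun's
predictor–corrector, classical RK4, and 4th-order
Adams–Bashforth–Moulton (PECE, RK4 start-up) — and every trajectory is
scored against the exact affine propagator (a matrix exponential, so
"truth" carries no discretisation error of its own).

## Worked example

```python
import dcmodel as dc

params = dc.default_parameters()        # λ=0.85, δ=0.05, μ=0.02, γ=0.5, ν=0.05, I=6e6
anchor = dc.anchored_truth_fixture()    # canonical t=5 state on the reference trajectory

table = dc.error_table("rk4", anchor.state, params, dt=1.0)
print(table.frame.to_string(index=False))
```

prints

```
    t         C_num        C_true  err_C_pct          N_num         N_true  err_N_pct
 5.00 90,880,136.51 90,880,136.51 0.00000000 150,047,685.76 150,047,685.76 0.00000000
10.00 90,657,023.87 90,657,024.59 0.00000080 149,681,776.42 149,681,776.36 0.00000004
15.00 90,507,781.52 90,507,781.43 0.00000010 149,437,930.27 149,437,930.11 0.00000010
20.00 90,408,340.82 90,408,340.72 0.00000010 149,275,456.33 149,275,456.17 0.00000010
```

`C_num` is the RK4 trajectory with a one-year step launched from the t=5
anchor state; `C_true` the exact propagation of the same state; the error
columns are percentage errors — RK4 tracks the 90-million-person
complications compartment to better than one person in a billion per
15-year horizon. Swapping `"rk4"` for `"explicit_euler"` raises the t=20
error to ≈0.011 %. The long-run equilibrium for these parameters is
`C* ≈ 90,209,790`, `N* ≈ 148,951,049`:

```python
eq = dc.equilibrium(params)             # Equilibrium(C_star=90209790.21..., ...)
dc.analyze(params).classification       # node, asymptotically_stable
```

The same stages are exposed as a CLI:

```
dcmodel stability                 # χ₁ = −0.0812, χ₂ = −1.4088 → stable node
dcmodel simulate --method rk4 --dt 1 --anchor printed_t5
dcmodel sweep-dt                  # step-size sweep 0.1–1.5 across all schemes
dcmodel report --out-dir results  # full reproduction: all tables and sweeps
```

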