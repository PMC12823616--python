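# Methods

This note documents the numerical design of the solver: the model, the
discretization, the choices made where the design was genuinely open, and
what the validation battery does and does not establish.

## Model and assumptions

The delayed fractional SIR system treats a closed population (no
demography, migration or vaccination) over an epidemic-scale horizon, with
constant rates. The Caputo derivative of order α ∈ (0, 1] on each
compartment introduces a power-law memory kernel; α = 1 is the classical
ODE limit. A single discrete delay τ (the incubation period) enters only
through the transmission term S(t)·I(t-τ). Generalized initial conditions
are history functions on [-τ, 0]; the initial state is their value at 0.

Under Caputo dynamics the rates formally carry units time^-α. They are
taken at face value and not rescaled when α varies — α-sweeps therefore
compare memory kernels at fixed nominal rates, which is the convention the
benchmark scenario implies.

## Basis

Daubechies order N (default db4, supported 2–10): enough smoothness for
Caputo orders ≤ 1 while keeping the support [0, 2N-1] short. Filters come
from the PyWavelets tabulation and are re-verified against the defining
normalization/orthonormality/vanishing-moment identities at construction
(db2's closed form is additionally pinned in the tests). The scaling
function is tabulated by the cascade algorithm — exact integer values from
the eigenvalue-1 eigenvector of the two-scale transition operator, then
dyadic refinement — at spacing 2^-12, with linear interpolation between
table points. Derivative tables use zero-padded central differences, which
keeps translate sums cancelling exactly (the derivative of the partition
of unity is zero); db2's limited regularity is flagged in the basis
summary diagnostics.

The interval [0, T] is handled by **periodization** of the level-J
translates (t ↦ t/T, division by √T): orthonormality and reproduction of
constants are then exact, with no boundary-corrected constructions. The
cost is an O(1) wrap-around defect when representing non-periodic
functions. Measured on midpoint interpolation of a smooth non-periodic
function, that defect confines itself to a boundary layer but decays only
first-order in integrated norms. The solver therefore augments the span
with one **trend function**: the L2-normalized residual of fitting t by
the wavelets. The augmented span equals span{wavelets} ∪ {t}; because the
raw monomial is nearly reproduced away from the boundary (vanishing
moments), using the residual rather than t itself keeps the collocation
matrix condition number moderate (≈3e4 at J = 6, growing with J — levels
beyond J ≈ 8 are not recommended). With this single extra function the
integrated interpolation error of smooth non-periodic targets drops by
roughly two orders of magnitude at J = 6.

A `full_mra` basis mode (level-J scaling plus level-J wavelet translates,
spanning the next resolution level in mixed form) exists for fidelity to
the textbook multiresolution expansion; the solver default is
`scaling_only` plus the trend, which spans the same spaces per degree of
freedom.

## Fractional operators

The Riemann–Liouville integral is computed by the product-trapezoidal
rule: the weakly singular kernel (t-s)^{α-1} is integrated exactly against
a piecewise-linear interpolant of the integrand (the same quadrature
family as the fractional Adams corrector), with 4·n_b panels by default.
Because quadrature acts linearly on samples, applying the operational
matrix P_α to a coefficient vector is identical to quadrature of the
reconstructed function — accuracy is governed by the smoothness of the
*combination*, not of individual (rough) wavelets. The Caputo derivative
is implemented as I^{1-α} ∘ d/dt (the m = 1 definition); the operational
formulation "fractional integration composed with differentiation" is
read the same way, since the literal alternative I^α ∘ d/dt is
dimensionally inconsistent with the definition. Collocation matrices are
assembled in physical space (values at nodes); the Galerkin matrix of
inner products is also available and cross-checked against the physical
action on smooth span members.

The Mittag-Leffler function (validation only) uses the power series with
adaptive truncation, switching for α < 1 and arguments below -5 to the
completely monotone spectral-integral representation; E_{1/2} is pinned
against scipy's erfcx closed form, E_1 against exp, E_2 against cos.
Supported range |z| ≤ 50.

## Delay handling

The shift matrix T_τ holds Lagrange interpolation weights (order 1 or 3,
default 3) mapping node values to node-minus-τ values. Stencils near grid
edges are one-sided rather than order-reduced: any four distinct nodes
reproduce cubics exactly, which keeps the delay path exact on the
polynomial fixtures. Nodes with t - τ < 0 read the prescribed history
directly (rows left empty in the matrix). A **cyclic** policy — wrapping
the lookup in index space, rolling the value vector *forward* by τ/h
positions — exists solely to reproduce the standard worked permutation
example; wrapping pre-history onto future times has no epidemiological
meaning, so `history` is the solver policy. The worked example's forward
roll is itself inconsistent with a backward time shift evaluated at the
nodes; the cyclic mode reproduces the printed matrix as printed.

## Collocation system and iteration

Unknowns are the coefficients of the *Caputo derivatives* g_X, not of the
compartments: reconstruction X = X(0) + I^α g satisfies initial data
exactly and keeps the t = 0 kernel singularity out of the residual (the
two formulations are algebraically equivalent on the span). Collocation
nodes are midpoints t_ℓ = (ℓ + ½)T/n_c with n_c = n_b = 2^J + 1 — a
square system that never touches t = 0. One global solve covers [0, T]
(no method of steps); residuals of the three equations are driven to an
∞-norm of 1e-10 (default) by Newton iteration with analytic Jacobian —
the Hadamard-product nonlinearity gives diagonal-times-matrix blocks — a
halving line search down to 1/64 that never accepts an uphill step, at
most 50 iterations, and zero initial coefficients (constant compartments
at the initial state). A finite-difference Jacobian is kept for
verification. Two fallbacks exist: a Picard iteration preconditioned by
the basis matrix (also selectable as `method="fixed_point"`), and
continuation in β (solve with transmission scaled down, warm-start
upward), which handles strong outbreaks over long horizons where the zero
start leaves Newton's basin.

Conservation is structural: the three right-hand sides cancel and the
three equations share P_α, so the residual sum equals Ψ(A_S + A_I + A_R);
at convergence the coefficient sums vanish to solver tolerance and
S + I + R - N stays at the 1e-15 level in practice (1e-6 is asserted).

**Resolution caveat.** The discrete nonlinear system can possess spurious
roots when the basis is too coarse for the dynamics: an α = 1 outbreak
over T = 30 converged cleanly at J = 6 to a trajectory with half the true
peak, while J = 7 agreed with RK4 to 5e-4. Long horizons or sharp peaks
need J ≥ 7, and agreement with the Adams oracle is the recommended check
whenever the regime changes.

## Reference solvers

*Fractional Adams–Bashforth–Moulton* (predictor–corrector, PECE with one
corrector sweep by default): rectangle-rule predictor and
product-trapezoid corrector convolution weights, delayed lookups by
linear interpolation of past steps (h ≤ τ enforced), optional forcing so
it can cross-check the manufactured fixtures. Its observed order is ≈2 on
smooth solutions, ≈1+α away from t = 0 on manufactured polynomial
solutions (whose fractional derivative has a t^{1-α} kink at the origin,
with a startup layer converging only linearly), and ≈1 in sup norm on
relaxation-type solutions with t^α behavior at 0 — the solver's 1e-3-step
runs are nonetheless accurate to ~1e-9 relative on the closed-form
fixture. *RK4 by the method of steps* (α = 1 only): fixed-step classical
RK4 per delay segment with cubic-Hermite dense output of the previous
segment for delayed lookups; fourth-order self-convergence is verified.

## Fixtures

Manufactured problems choose polynomial triples of degree ≤ 3 (so all
Caputo derivatives have exact Γ-ratio closed forms — no quadrature in the
verification chain), add the imbalance back as forcing, and take
histories as the polynomial restriction to [-τ, 0]. The exact triple
substituted at the nodes leaves an assembled residual at the 1e-14 level
for any α, certifying assembly, forcing and delay machinery jointly.
Full *recovery* to 1e-6 is asserted for degree ≤ 1 at α = 1, where the
derivative stays inside the span; for α < 1 the derivative t^{1-α} is not
representable and the scheme converges without being exact. The
Mittag-Leffler relaxation fixture (β = δ = 0) provides the closed forms
I₀E_α(-γt^α) and R(0) + γI₀t^α E_{α,α+1}(-γt^α).

The benchmark scenario ships with the published histories
(620 - 5t, 10 + 2t, 70 + 3t on [-2, 0], τ = 2, N = 700) in two variants,
because the published history functions and the published t = 0 table
values disagree on which of I and R starts at 70: `as_text` follows the
polynomials, `as_tables` swaps φ₂ and φ₃. Neither is silently preferred —
the CLI requires the choice. The rates β, γ, δ and the order α for that
scenario are not published anywhere; the defaults β = 5e-4, γ = 0.1,
δ = 0.05, α = 0.9 are placeholders chosen once for a plausible mild
outbreak (effective reproduction ratio βN/(γ+δ) ≈ 2.3, growth over a
10-day horizon) and are clearly marked as not sourced.

## What the tests show — and don't

The battery certifies internal consistency (operators against Γ-ratio and
Mittag-Leffler closed forms, semigroup and linearity identities),
cross-method agreement (three independent solution routes agreeing to
1e-3…1e-2 relative), structural conservation, and first-order-or-better
basis convergence on a fixture whose solution has a genuine t^α
singularity. It does not calibrate the model to any epidemic data — the
scenario's rates are placeholders — so conclusions about real influenza
dynamics require fitting β, γ, δ, α, τ to observations first. Problem
sizes throughout (J = 4…7, oracle steps 1e-3, horizons 10–30) are chosen
so the full suite runs in well under a minute of compute per module while
leaving each asserted tolerance at least an order of magnitude of slack.

## Known limitations

- Single shared discrete delay; no distributed or state-dependent delays.
- Orders α ∈ (0, 1] only; no Riemann–Liouville or Atangana–Baleanu
  derivative operators.
- Periodized-plus-trend basis conditioning grows with J; J > 8 is not
  useful in double precision.
- The Mittag-Leffler evaluator covers real arguments |z| ≤ 50 (general
  second parameter only on the series range).
- No stability/bifurcation analysis of the model; no data fitting.
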