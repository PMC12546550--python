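# Methods

## Model

`angiosim` integrates a one-dimensional continuum model of tumor-induced
angiogenesis on the tissue strip `Ω = [0, L_f]` between a parent vessel at
`x = 0` and a tumor at `x = L_f`. Five dimensionless fields evolve in time:
endothelial cell density `C`, protease `P`, inhibitor `I`, extracellular
matrix (ECM) density `F`, and oxygen `O`:

```
∂C/∂t = ∂/∂x[ d_C ∂C/∂x − C(α₁ ∂F/∂x − α₂ ∂I/∂x + α₃ ∂φ/∂x) ] + k₁ C(1−C) H(O)
∂P/∂t = d_P ∂²P/∂x² − k₃ P I + k₄ T C + k₅ T − k₆ P
∂I/∂t = d_I ∂²I/∂x² − k₃ P I
∂F/∂t = −k₂ P F
∂O/∂t = d_O ∂²O/∂x² − γ₁ C O/(K_O + O) + γ₂ (O_max − O) β C
```

with homogeneous Neumann (no-flux) conditions at both endpoints for every
field. `H(O) = O/(K_O + O)` is the Michaelis–Menten saturation of
oxygen-limited proliferation and consumption. The tumor angiogenic factor
is the fixed profile `T(x) = exp(−(L_f − x)²/ε)` peaking at the tumor edge;
cells respond to its logarithmic regularization
`φ(x) = α₄⁻¹ log(1 + α₄ T(x))`, which caps the effective taxis velocity
where `T` is steep.

Modelling assumptions worth keeping in mind:

* `α₂` is *negative* by the model's sign convention and enters the flux as
  `−α₂ ∂I/∂x`, so the effective inhibitor-gradient coefficient is
  `+|α₂|` — cells drift up inhibitor gradients. This is counterintuitive
  biologically, but it is the stated convention of the governing
  equations; we implement it verbatim and do not reinterpret signs.
* The ECM equation has no transport term: matrix is degraded in place.
* Oxygen supply is proportional to local endothelial density — nascent
  vessels are assumed immediately perfused, with functionality factor `β`.

## Discretization

**Space.** Method of lines on `M + 1` equidistant nodes `x_j = j·Δx`,
`Δx = L_f/M`, with `M ≥ 4`. The discrete gradient `D_x` uses central
differences in the interior and second-order one-sided stencils
`(−3, 4, −1)/(2Δx)` / `(1, −4, 3)/(2Δx)` at the boundary rows. The
discrete Laplacian `D_xx` is the standard three-point stencil with
boundary rows `(−2, 2)/Δx²` and `(2, −2)/Δx²`, i.e. the ghost-node
reflection `u₋₁ = u₁` implied by zero flux. Both operators annihilate
constants row by row, `D_x` is exact on quadratics, and `D_xx` conserves
trapezoidal-weighted mass exactly (the weighted column sums telescope to
zero). The full eigensystem of `D_xx` is closed-form:
`λ_m = −(4/Δx²) sin²(mπΔx/(2L_f))` with cosine eigenvectors
`cos(mπj/M)` — this is verified against numeric eigendecompositions to
1e−10 for `M ≤ 64` and drives the stability bounds below.

The advective flux in the C-equation is assembled exactly as the
semi-discrete system states it: `D_x(C ⊙ (α₁ D_x F − α₂ D_x I + α₃ D_x φ))`,
with `D_x φ` precomputed *discretely* from the sampled `φ` (not the
analytic derivative), so the implemented scheme is literally the printed
operator composition. The right-hand side splits as `L(U) + N(U)` with
`L` the linear diffusion block (zero row for `F`) and `N` the advection
and reactions; the integrator treats both together, fully explicitly.

**Time.** Classical four-stage RK4 with fixed step. Stage evaluations
occur at `t, t + Δt/2, t + Δt/2, t + Δt`; for the autonomous physical
model this is the plain autonomous scheme, and it preserves fourth order
when time-dependent manufactured sources are present. Stage vectors are
named `stage_1..stage_4` in code because `k₁..k₆` are kinetic rates.

**Step-size bounds** (`compute_stability_limits`):

* diffusion: `Δt ≤ Δx²/(2 d_max)`, `d_max = max{d_C, d_P, d_I, d_O}` —
  the forward-Euler spectral bound at the stiffest Laplacian mode
  `λ = −4/Δx²`. For RK4 this is conservative: the real-axis stability
  interval `[−2.785, 0]` admits steps up to `1.3925×` this bound, and the
  test suite pins both facts empirically (bounded at `0.95×` and at
  `1.3×`, divergent at `1.4×`).
* advection: `Δt ≤ C_CFL·Δx`. The CFL constant is never quantified by the
  model's theory; when a state is available we use the measured maximum
  advective speed `max_j |α₁(D_xF)_j − α₂(D_xI)_j + α₃(D_xφ)_j|` (and
  `1/a_max` as the constant), otherwise a conservative default
  `C_CFL = 1`. Speeds at round-off level are treated as zero and yield an
  infinite CFL bound.
* invariant region: `Δt ≤ min{Δx²/(2d_max), 1/L_R, Δx/α_max}` where
  `L_R` is a Lipschitz constant of the reactions over the invariant box.
  `L_R` is estimated numerically as the largest ∞-norm of a
  forward-difference 5×5 reaction Jacobian over a 3-level Cartesian
  sample of the box at both tumor-factor extremes (`T ∈ {0, 1}`); for the
  baseline parameters this gives `L_R ≈ 0.78`.

`dt_recommended` is 0.9 × the smallest applicable bound; `simulate`
refuses larger steps unless explicitly overridden.

## Parameters

Baseline values (dimensionless): `d_C = 0.001`, `d_P = d_I = 0.01`,
`d_O = 0.1`; `α₁ = 0.1` (haptotaxis), `α₂ = −0.1` (inhibitor response),
`α₃ = 0.01` (TAF response); `k₁ = 0.1` (proliferation), `k₂ = 0.05` (ECM
degradation), `k₃ = 0.5` (protease–inhibitor binding), `k₆ = 0.2`
(protease decay); `γ₁ = 0.1` (max O₂ consumption), `γ₂ = 0.05` (vascular
supply), `K_O = 0.2` (half-saturation). Six parameters have no published
baseline and carry package defaults, flagged as such by `params --show`
and in all run metadata: `k₄ = 0.1`, `k₅ = 0.05` (protease production),
`β = 1`, `O_max = 1`, `ε = 0.01` (TAF width² scale), `α₄ = 1`
(regularization strength). These are mid-range magnitudes consistent with
the baseline set. Sign conventions (all positive except `α₂ < 0`) are
enforced at construction.

Baseline scenario initial data: `C = 1` on `0 ≤ x ≤ 0.1` (the node at the
cutoff is seeded — the condition is inclusive) and 0 beyond; `P = 0.1`,
`I = 0.2`, `F = 1` uniform; `O = 0.5 e^{−5x} + 0.1`. The default run uses
`M = 256`, `Δt = 10⁻⁵`, `T_f = 10`.

## Invariant region and energy

The continuous solution stays in the box `C ∈ [0,1]`,
`P ∈ [0, max{ξ₁, (k₄+k₅)/k₆}]`, `I ∈ [0, ξ₂]`, `F ∈ [0, ξ₃]`,
`O ∈ [0, max{O₀+ξ₄, O_max}]` (for the defaults: `P_max = 0.75`, oxygen
ceiling 1). The monitor *verifies* this claim on discrete trajectories —
it never clips or projects a state; violations are detected with an
absolute tolerance (default 1e−10) to absorb round-off, recorded once per
component at first occurrence, and by default warn rather than abort.
Running per-step global extrema are tracked at every accepted step; the
sampled min/max series and the energy

`E(t) = ½ ∫ (C² + P² + I² + F² + O²/(γ₂β)) dx`

(trapezoidal quadrature, the same weights under which the discrete
Laplacian conserves mass) are recorded at the configured cadence. The
energy trace is a dissipativity diagnostic only; no decay-rate constants
are computed.

For the baseline run the recorded extrema are `C ∈ [0, 1]`,
`I ≤ 0.2`, `F ∈ [0.96, 1]` (pointwise nonincreasing), `O ∈ [0.103, 0.6]`,
with zero violations at tolerance 1e−10 over the full horizon, and the
energy decays from 1.123 to 0.872.

## Manufactured-solution verification

Two closed-form solution sets are provided. The `paper` variant uses
sine-based `C` and `I` whose spatial derivative does **not** vanish at
the endpoints — it is retained verbatim for reference, but it is
incompatible with the no-flux boundary rows, so boundary accuracy
degrades unpredictably and it is not used for order assertions. The
`neumann_compatible` variant replaces those two fields with cosine modes
(`C = ½(1+cos πx)e^{−0.1t}`, `I = 0.2 cos(2πx)e^{−0.3t}`), leaving the
others unchanged; every field then has zero slope at both endpoints.
Sources `S_u = ∂t u_e − RHS(u_e)` are derived symbolically with sympy
once per study and lambdified; the forced residual is identically zero by
construction and is additionally re-verified in tests with an
independently assembled right-hand side (closed-form spatial derivatives,
finite-difference time derivative).

**Norm.** Errors are measured in the Δx-weighted discrete L2 norm
`sqrt(Δx Σ (u_j − u_e(x_j))²)`, consistent with the continuous L2 norm.
Because the reference tables' norm convention, final time and step policy
are not published, absolute error magnitudes are not comparison anchors —
only observed rates `log2(e_coarse/e_fine)` are.

**Spatial study** (`run_spatial_convergence`): grids doubling from 32 to
256, `T_f = 1`, step slaved to `0.5 × Δx²/(2 d_max)` per grid so temporal
error is negligible. The study's default parameter set equals the
baseline except `ε = 0.09`: MMS methodology requires every coefficient
field to be resolved on the *coarsest* grid, and the scenario's
`ε = 0.01` gives the TAF profile a width of ~3 cells at `M = 32`, which
leaves the coarse rows pre-asymptotic (the P-component rate then reflects
cancellation between its own error and the C-coupling error localized at
the tumor edge, drifting to 2.1–2.8). With the resolved width
(`sqrt(ε) = 0.3` ≈ 10 cells at `M = 32`) all five components converge at
observed rates 1.99–2.06.

**Temporal study** (`run_temporal_convergence`): fixed grid, halving
steps, either against the exact fields (`exact_continuous`, which
plateaus at the grid's spatial error floor) or against a reference run at
`min(Δt)/4` on the same grid (`self_reference`, isolating temporal
error). With the baseline kinetics the fourth-order temporal error at any
diffusion-stable step lies *below double-precision round-off* (measured
1e−13 to 1e−16), so observed rates there are noise; the study therefore
defaults to a reaction-dominated verification configuration (kinetic and
exchange rates scaled to O(1)–O(10), `M = 16`,
`Δt ∈ {10⁻², 5·10⁻³, 2.5·10⁻³}`), where the temporal error is well
resolved and all five components show observed order 4.0–4.15. A
verification study is free to choose such a configuration: the order of
an integrator is a property of the scheme, not of one parameter set.

## What the studies do and do not show

The manufactured fields are smooth, slowly decaying trig/exponential
profiles; they exercise every term of the discretization but none of the
sharp-front dynamics of the physical scenario (discontinuous endothelial
seeding, steep TAF profile). Conversely the scenario run exercises the
fronts but has no exact solution; its correctness evidence is the
invariant-region and mass-conservation behavior, not an error norm.
Passing both therefore supports — but, as always with verification on
synthetic problems, does not prove — correctness on real applications.
The sensitivity sweep's metrics (EC front position at threshold 0.5,
arrival time at `0.9 L_f`, oxygen extrema, trapezoidal EC mass) are this
package's own scalar summaries of qualitative behavior, resolved at the
snapshot cadence.

## Numerical choices and degenerate inputs

* Fixed-step loop; a final shorter step closes any remainder to land
  exactly on `T_f`. `T_f = 0` returns the initial state.
* Negative transient values are passed through unmodified — positivity is
  a verified property, not an enforced one.
* Non-finite states abort with the failing time and component; RK4 stage
  failures name the stage. Finiteness is checked on every stage result in
  the public single-step API and every 128 steps in the hot loop.
* No randomness anywhere in the integrator: reruns are bit-identical on
  one platform.
* Grid construction rejects `M < 4` (the one-sided boundary stencils span
  three nodes each and must not collide).
* `observed_rate` rejects nonpositive errors; convergence drivers record
  per-resolution failures (e.g. instability aborts) in the table rather
  than failing the study.

## Problem sizes

Default study sizes were chosen so the full verification battery runs on
a single CPU in minutes: the spatial ladder tops out at `M = 256`
(≈26 000 steps at the slaved step), the temporal study at `M = 16`
(≈2 000 steps including the reference run), and the baseline scenario is
`M = 256` × 10⁶ steps (a few minutes of wall time).

## Known limitations

* 1-D only; no higher-order stencils, non-uniform grids, or implicit /
  IMEX / adaptive stepping (fully explicit RK4 by design).
* The advective CFL constant is a measured estimate, not an analytic
  bound; `L_R` is a sampled numerical estimate of a Lipschitz constant.
* The `paper` manufactured variant's boundary incompatibility is
  documented, not repaired.
* Energy-decay constants and attractor/absorbing-set estimates are out of
  scope; the energy trace is diagnostic only.
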