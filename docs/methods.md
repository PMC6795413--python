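# Methods

## Dual and multi-dual scalars

`DualScalar` implements `x + y·ε` with `ε² = 0`; `MultiDualScalar`
implements `x + Σᵢ yᵢ·εᵢ` with `εᵢεⱼ = 0` for *all* i, j (including i = j),
so `n` directional derivatives share one real-part computation. Both types
overload `+ − * / **`, unary negation, `abs`, comparisons and the
elementary functions `exp, log, sqrt, sin, cos, tanh, power`; plain numbers
promote implicitly (dual part 0), so model code written for floats runs
unchanged.

Numerical conventions where the derivative is genuinely ambiguous or
undefined:

- `abs` at 0 uses the symmetric subgradient choice sign(0) = 0.
- `maximum`/`minimum` with equal real parts return the **first** argument
  (and its dual parts) — the deterministic tie-break a hand-written
  `if a >= b` would produce.
- `0**p` with `0 < p < 1`, and `sqrt`/`log` at or below 0, raise a domain
  error naming the function and the offending value rather than emitting an
  infinite dual part. Failing loudly beats silently corrupting a gradient.
- Comparisons order by the real part only, so control flow in overloaded
  code follows the nonlinear trajectory. This is the piecewise
  linearization implicit in all operator-overloading forward AD: the
  derivative is exact within each smooth branch.

Multi-dual coefficients are stored as a dense float64 vector. Per
coefficient, every operation performs the identical IEEE-754 sequence as
the corresponding single-dual operation, which is why the multi-dual
adjoint reproduces the brute-force adjoint *bitwise* (the engine also keeps
the final dot-product reductions in identical memory order for the same
reason). Sparsity is exploited at the segment level, not inside the scalar.

## TLM, adjoint, and the segmented sweep

`evaluate_tlm` wraps the state in dual scalars seeded with the perturbation
and returns the dual part of one evaluation; the real part is bitwise equal
to the plain nonlinear evaluation. `adjoint_bruteforce` rebuilds the
Jacobian column by column with `n` unit-seeded TLM calls;
`adjoint_multidual` does the same with one `n`-part call (an optional
`chunk_size` splits the seeds over several calls to bound memory; the
default uses the full footprint).

`adjoint_segmented` composes per-segment adjoints in reverse order,
each linearized about the state *entering* that segment along the stored
nonlinear trajectory (checkpointing granularity = one segment). For the
pointwise biology segment the update is `w + dt·Σₚ Jₚᵀw` with each process
Jacobian built per cell from one multi-dual tendency evaluation of seed
dimension |readsₚ| (grazing: 5, growth: 4–5, remineralization: 4 — versus
`n` = 11 × n_layers for the monolithic routes). Declared footprints may
over-declare but never under-declare; `verify_footprints` perturbs
out-of-footprint variables and requires a bitwise-zero response (tolerance
exactly 0). A composition check against the monolithic evaluator guards
against incomplete segment lists.

Verification machinery: `dot_product_test` draws seeded Gaussian pairs
(u, w) and reports |⟨Mu, w⟩ − ⟨u, Mᵀw⟩| / (|⟨Mu, w⟩| + tiny) per trial
(pass ≤ 1e−12); `taylor_test` halves a step h over 8 levels from h₀ = 1e−2
and fits the log–log slope of the second-order remainder, excluding points
below the floor 1e−13·(|J| + 1); a correct gradient gives slope ≈ 2, a 1%
gradient error collapses it to ≈ 1.

## The ecosystem column model

Eleven prognostic variables per layer (PS, PL, ZS, ZL, ZP, NO3, NH4, DON,
PON in mmol N m⁻³; SiOH4, Opal in mmol Si m⁻³) on a single vertical column
(default 5 × 5 m layers, dt = 1 h). Composition order per step — fixed and
identical in nonlinear, TLM and adjoint paths — is transport → light →
biology → sinking.

The formulation follows the standard NEMURO process set, parameterized so
every term is an explicit transfer between compartments: Michaelis–Menten
uptake of NO3 (ammonium-inhibited, `exp(−ψ·NH4)`) and NH4, a multiplicative
Michaelis–Menten silicon factor for the diatoms (a smooth stand-in for a
Liebig minimum), Steele light limitation `(I/I_opt)·exp(1 − I/I_opt)`,
Ivlev grazing `g_max·(1 − exp(λ(P* − P)))` with the threshold `P*`
defaulting to 0 (the smooth configuration; a positive threshold engages the
`maximum(0, ·)` convention for piecewise-smooth testing), linear +
quadratic mortality, egestion/excretion split by assimilation and
gross-growth efficiencies (α = 0.7, β = 0.3), decomposition
PON → DON → NH4, nitrification, and opal dissolution. Diatom shell silicon
is carried implicitly as `r_si_n·PL`; all PL losses route the corresponding
silicon to Opal. Consequently total nitrogen per cell and total silicon
(SiOH4 + Opal + r_si_n·PL) are conserved by the source step to rounding
error — a strong structural test independent of the AD machinery. An
optional Q10 temperature factor exists and is off by default; forcing is a
diurnally constant surface irradiance (150 W m⁻²), the smallest faithful
configuration.

Parameter defaults are NEMURO-style magnitudes (growth 0.4–0.8 d⁻¹,
grazing 0.1–0.4 d⁻¹, sinking 40 m d⁻¹, attenuation 0.04 m⁻¹ water +
0.03 m² (mmol N)⁻¹ self-shading, chlorophyll 1.59 mg chl (mmol N)⁻¹); they
characterize a plausible mid-latitude column, with no claim to reproduce
any particular site, and are fully overridable through the config file.

Transport is explicit flux-form vertical diffusion (stability number
κ·dt/(Δz·Δz̄) ≤ 0.5 enforced at grid construction), self-adjoint under the
volume-weighted inner product; its Euclidean transpose is hand-coded, as is
the transpose of the first-order upwind sinking operator (CFL ≤ 1
enforced) and the analytic adjoint of the light map. By default these
three segments bypass dual arithmetic — mirroring systems where transport
adjoints pre-exist — and the all-dual route is retained as a cross-check
(`use_hand_adjoints=False`); the two paths agree to ≤ 1e−12.

Positivity is never clipped inside differentiated code (clipping destroys
TLM/adjoint consistency). The public source-step operation rejects negative
inputs by contract; the assimilation trajectories run without that per-step
check because linearization states and intermediate analyses may leave the
positive cone by rounding-level amounts, where all rate expressions remain
smooth (half-saturations ≥ 0.1 bound the singularities well away from the
states encountered).

## Incremental 4D-Var

Cost: `J(δx) = ½δxᵀB⁻¹δx + ½Σₖ(Hₖ(xₖ) − yₖ)ᵀR⁻¹(Hₖ(xₖ) − yₖ)` with the
trajectory launched from background + δx. B and R are diagonal — the
desk-scale choice that keeps the system transparent; operational systems
usually carry multivariate background correlations, and nothing in the
machinery depends on the diagonal assumption. H samples a state variable
directly or the linear chlorophyll diagnostic.

Each outer loop (default 2) re-runs the nonlinear trajectory, freezes the
innovations, and minimizes the quadratic incremental cost by conjugate
gradients (default 10 iterations, relative-residual tolerance 1e−10 as a
secondary stop). With preconditioning on (default) CG runs in the control
space `v = B^{−1/2}δx`, where the Hessian is `I + B^{1/2}GᵀR⁻¹GB^{1/2}`.
Each Hessian product costs exactly one TLM sweep and one adjoint sweep of
the window; the right-hand side costs one extra adjoint sweep per outer
loop, and the full run uses n_outer + 1 nonlinear trajectories (the last
for closing diagnostics) — all instrumented. The recorded quadratic cost
uses the exact CG decrease `½α‖r‖²` per iteration and is therefore
non-increasing by construction; non-positive curvature (the signature of an
inconsistent TLM/adjoint pair) raises a diagnostic pointing at the
dot-product test. Observation times are integer step indices; a helper
snaps physical times to the nearest step with ties rounding down.

## Twin experiments

The truth initial condition is the background scaled componentwise by
`exp(scale·z)`, z ~ N(0, 1) — a lognormal relative perturbation (default
scale 0.2) that preserves positivity and reduces to the background exactly
at scale 0. The observing system emulates a coupled physical–biogeochemical
setting with two streams at the surface cell: a dense, gapless stream of
one designated state variable (default NO3, every step — the analog of a
gap-filled gridded surface product) and surface chlorophyll with a
*contiguous* block of time slots removed (default 30% — a cloud-cover
analog; contiguity, rather than i.i.d. dropout, mimics weather systems).
Noise is Gaussian with the same stds used as R in the assimilation
(perfectly specified errors, isolating machinery correctness from
misspecification effects); when a stream's noise is set to 0 the R std
falls back to a documented default so R stays positive definite.
Background stds are 0.3 × background with an absolute floor of 0.02.
The default window is 96 × 1 h steps — a 4-day cycle; the window length at
this grid scale is a free design choice.

The improvement metric is `|y − H(prior)| − |y − H(posterior)|` per record
(positive = the assimilation reduced the misfit), summarized by mean,
median and histogram counts over 20 bins spanning ±5 observation stds.
Initial-condition recovery is reported as relative RMS against the truth.
Everything — truth, noise, mask placement — derives from a single seed, so
an experiment is a pure function of (configuration, seed), bitwise.

What the twin setup does *not* emulate: three-dimensional circulation,
real observation-operator complexity (satellite averaging kernels,
retrieval biases), correlated or misspecified observation errors, and
model error (the strong-constraint assumption is exactly satisfied by
construction). Passing twin tests therefore demonstrates the correctness
of the differentiation and minimization machinery, not skill on real data.

## Problem sizes and tolerances

Verification uses 2-layer (n = 22) and 5-layer (n = 55) columns: brute-force
adjoints and dense finite-difference Jacobians are exact-oracle-checkable
there, and every structural property (footprints, conservation, adjoint
identities) is size-independent. The finite-difference oracle uses central
differences with step 1e−6·(1 + |xᵢ|) and a 1e−6 relative tolerance — the
standard truncation/rounding compromise; dual-based routes are compared to
each other at 1e−12 relative (they differ only by summation order) and
bitwise where the operation sequences coincide. The acceptance script runs
the default 96-step twin experiment unchanged.
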