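# dualda

Dual-number automatic differentiation that turns plain nonlinear model code
into exact tangent linear and adjoint models, demonstrated on an
11-variable NEMURO-type plankton ecosystem column model inside an
incremental strong-constraint 4D-Var data-assimilation system.

## Who this is for

Developers of biogeochemical (or other mostly-pointwise) models who need
tangent linear and adjoint code for variational data assimilation but do
not want to hand-derive and line-by-line transpose their model — a
notoriously error-prone effort that must be repeated after every model
change. With dual numbers, the derivative machinery *is* the nonlinear
code: change the model, and its TLM and adjoint update themselves.

## The idea

A dual number `d = x + y·ε` extends the reals with a nilpotent element,
`ε² = 0`. Pushing it through any differentiable expression gives

```
f(x + y·ε) = f(x) + f′(x)·y·ε
```

exactly — the dual part carries the derivative with no truncation error.
For a vector model `M_NL: Rⁿ → Rⁿ` the same identity reads

```
M_NL(x_NL + x_TL·ε) = M_NL(x_NL) + M(x_NL)·x_TL · ε
```

so **one** dual evaluation of the nonlinear model yields the tangent linear
product `M(x_NL)·x_TL`. The adjoint product `M(x_NL)ᵀ·x_AD` is
reconstructed column by column,

```
Mᵀ·x_AD = Σᵢ eᵢ · ⟨M·eᵢ, x_AD⟩ ,
```

using either `n` dual evaluations, a single evaluation with `n` mutually
annihilating dual parts (`εᵢεⱼ = 0`), or — the interesting case — a
*segment-restricted* sweep: biogeochemical models decompose into process
segments (growth, grazing, mortality, remineralization, …) that each read
only a few variables and act pointwise per grid cell, so the effective seed
dimension drops from `n` to the per-cell read-set size (e.g. 5 plankton
variables for grazing, never the nutrients). Vertical transport, sinking
and light attenuation — the only non-pointwise segments — carry hand-coded
linear/analytic adjoints.

The adjoint drives a textbook incremental strong-constraint 4D-Var
minimization (diagonal B and R, control-variable transform `v = B^{-1/2}δx`,
conjugate gradients; 10 inner iterations × 2 outer loops by default) that
adjusts the initial conditions of the column model to fit synthetic
observations: a dense, gapless surface nitrate stream and a cloud-masked
surface-chlorophyll stream.

## A worked example

```python
from dualda import DualScalar

def f(x):                      # f'(x) = 4(x - 1)
    return 2.0 * (x - 1.0) ** 2 + 3.0

r = f(DualScalar(3.0, 1.0))
print(r.real, r.dual)          # 11.0 8.0  — value and exact derivative
```

`examples/02_tlm_adjoint_verification.py` builds a 2-layer column model
(`n = 22`) and verifies the adjoint routes:

```
bruteforce vs multidual bitwise identical: True
segmented vs bruteforce max rel diff: 5.77e-16
evaluator calls, bruteforce: 22 (= n)
evaluator calls, multidual:  1
  biology:grazing: 5          # adjoint seed dimension, vs n = 22
dot-product identity max discrepancy over 10 trials: 4.11e-15 (PASS)
```

The brute-force and multi-dual adjoints agree *bitwise* (identical
floating-point operation sequences per dual coefficient), the segmented
adjoint agrees to rounding error while propagating far fewer derivative
coefficients, and the TLM/adjoint pair satisfies ⟨Mu, w⟩ = ⟨u, Mᵀw⟩ to
4×10⁻¹⁵.

`examples/04_twin_assimilation.py` runs a 2-day twin experiment:

```
nonlinear cost per outer loop + final: 925.25 -> 31.61 -> 31.61
mean improvement [NO3]: +0.4915 (positive = misfit reduced)
mean improvement [chlorophyll]: +0.0852 (positive = misfit reduced)
```

The 4D-Var analysis cuts the cost by ~97% and reduces the absolute
model–observation misfit for both observation streams (improvement =
|y − H(prior)| − |y − H(posterior)| per record).

A thin CLI wraps the same library calls: `dualda simulate | tlm | adjoint |
jacobian | check | assimilate | twin` (see `dualda --help`).

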