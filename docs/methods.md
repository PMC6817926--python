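# Methods

## Model and scaling

The package works with the dimensionless reaction–diffusion system

    U_t = U − U² − UV − UV²,
    V_t = V_XX − k₁k₂ V − k₁V² + k₁UV + k₁UV²,

for a prey density `U` and predator density `V`.  The quadratic predation
term `UV` is the classical one; the cubic term `UV²` models two predators
feeding together on one prey during the mating period — it removes prey and
recruits predators.  Prey carry no diffusion; the predator diffusivity is
scaled to one.

Two dimensionless composites control the dynamics.  `k₁ = √(a₁a₄)/a₂`
compares pair predation (`a₄`) against intraspecific prey competition per
unit growth (`a₂²/a₁`): `k₁ > 1` exactly when `a₄ > a₂²/a₁`, and this is the
regime treated as biologically meaningful.  `k₂ = a₅/(a₁k₁)` is the scaled
predator mortality.  `model.nondimensionalize` implements only this (k₁, k₂)
map; the full space/time/density rescalings are not reproduced, and the
dimensionless form is primary throughout.  `k₁ = 1` is accepted when
constructing parameters but rejected by every solver operation with an
explicit "degenerate" error, because both solution families divide by
`k₁ − 1`.

Homogeneous steady states are extinction `(0,0)`, prey-only `(1,0)`, and
coexistence roots obtained from `U = (k₂+V)/(1+V)` in
`V³ + 2V² + V + (k₂−1) = 0` (real cubic roots polished by Newton; kinetics
at every returned point vanish below 1e−12).  Negative-density branches are
reported with a non-biological flag rather than suppressed.  No stability
analysis is performed; the `stability_tag` is a label only.

## Travelling-wave reduction and residual layers

With `U = u₁(ξ)`, `V = v₁(ξ)`, `ξ = X − cT`, the system reduces to

    (prey)      −c u₁′ = u₁ − u₁² − u₁v₁ − u₁v₁²,
    (predator)  −c v₁′ = v₁″ − k₁k₂v₁ − k₁v₁² + k₁u₁v₁ + k₁u₁v₁²,

and the *combined* ODE is their sum.  Residual operators follow the
"move everything to one side" convention, with the signs fixed so that the
combined residual is pointwise identical to the sum of the two system
residuals — an exact algebraic identity that doubles as a self-test (it is
asserted at 1e−12 on random smooth profiles).

This layering matters scientifically: the expansion methods annihilate only
the **combined** ODE.  Whether a family also satisfies the prey and predator
equations separately is an open question that the package deliberately does
not prejudge — `verify_sim.verify_family` reports all three residual layers
and asserts smallness only of the combined one.  At the reference pulse
parameters the separate system residuals are O(1), so the families should
be read as exact solutions of the combined equation, not of the original
system.

Derivatives of closed-form profiles are analytic (sympy expressions
differentiated exactly, then lambdified).  Arbitrary callables fall back to
second-order central differences evaluated at shifted points (steps 1e−6
for first, 1e−4 for second derivatives — chosen to balance truncation
against round-off at profile magnitudes of order one).  Poles of a profile
(coth-type branches) surface as NaN entries that are masked and counted,
never raised.

## Expansion engine

The engine follows the standard recipe: polynomial ansatz
`u₁ = Σ αᵢFⁱ`, `v₁ = Σ βᵢFⁱ` in a generator `F(ξ)`; degrees by homogeneous
balance (`u₁v₁²` of degree n+2m against `v₁″` of degree m+2, with the
quadratic terms forcing n = m, hence n = m = 1); substitution into the
combined ODE with `F′`, `F″` rewritten through the generator's auxiliary
ODE; coefficient collection per power of `F`; symbolic solution with `β₁`
kept free.  Constant terms α₀, β₀ are fixed to zero in the default pipeline
(the engine supports nonzero constants but they are not enabled).

Two auxiliary rules are implemented:

* **(G′/G) rule** `F′ = −F² − λF − μ`: everything rewrites polynomially and
  four coefficient equations result.  The cubic coefficient factors as
  `β₁(α₁β₁(k₁−1) + 2) = 0`, fixing `α₁ = −2/(β₁(k₁−1))` on every nontrivial
  branch.  The constant coefficient `−μ(c(α₁+β₁) − λβ₁) = 0` splits the
  solution set:
  - **Case I** — satisfied by constraining the speed,
    `c = λβ₁²(k₁−1)/(β₁²(k₁−1) − 2)`, with
    `μ = k₁k₂/2 + 1/(β₁²(k₁−1))` and
    `λ = 1/β₁ + k₁β₁/2 + 2/(β₁³(k₁−1)²)` from the linear coefficients.
  - **Case II** — satisfied by `μ = 0`; the remaining two equations leave a
    quadratic in λ, and both sign branches are returned (labelled `a`/`b`,
    ordered deterministically) rather than one being silently chosen.
  These closed forms are *derived* by the engine at run time, not stored;
  the tests pin them against independently known anchors.
* **quartic rule** `(F′)² = h₀ + h₁F + h₂F² + h₃F³ + h₄F⁴`: here
  `F″ = h₁/2 + h₂F + (3/2)h₃F² + 2h₄F³` rewrites, but a bare `F′` does not —
  its coefficient `c(α₁+β₁)` becomes the first equation and, for a
  travelling wave (`c ≠ 0`), forces `α₁ = −β₁`.  The rest solves linearly:
  `h₁ = 0`, `h₂ = 1 + k₁k₂`, `h₃ = 4k₁β₁/3`, `h₄ = (k₁−1)β₁²/2`, with `h₀`
  and the wave speed free.  The squared convention for the auxiliary ODE is
  deliberate: it is the convention under which the closed-form generator
  catalog below actually solves the equation (each entry is verified
  numerically against the defining ODE in the tests).

Back-substitution of every returned family into its source system must
simplify to zero *symbolically* (a ladder of expand/cancel/radsimp/simplify
is used; if sympy cannot prove zero the test fails — there is no silent
numeric fallback).  An independent numeric oracle additionally checks that
the collected polynomial equals direct substitution of the ansatz into the
combined ODE at random parameter tuples (tolerance 1e−9).

Degenerate zero-amplitude branches are returned tagged `trivial` rather
than dropped, so downstream code can see the full algebraic solution set.

## Generator catalogs

**(G′/G).**  The generator's three branches follow the sign of
`Δ = λ² − 4μ`: hyperbolic (kink-bearing), trigonometric, rational.  The
hyperbolic branch is evaluated through `tanh` to avoid `cosh` overflow.
The integration-constant default is `A₁ = 0, A₂ = 1` — the bounded
tanh-type kink; `A₁ = 1, A₂ = 0` is the coth-type branch with a pole at
`ξ = 0`, which is why it is *not* the default.  Kink plateaus
`−λ/2 ± √Δ/2` are recorded in metadata; they are exactly the fixed points
of the generator ODE.  Δ ≤ 0 branches are implemented for completeness and
labelled as outside the kink discussion.

**Quartic (h₀ = h₁ = 0).**  Implemented branches, each numerically verified
against `(F′)² = h₂F² + h₃F³ + h₄F⁴` on its validity domain:

| id | form | conditions |
|---|---|---|
| I.sech | `2h₂ sech(√h₂ξ)/(√δ₁ − h₃ sech(√h₂ξ))` | h₂>0, δ₁>0 |
| I.csch | `2h₂ csch(√h₂ξ)/(√(−δ₁) − h₃ csch(√h₂ξ))` | h₂>0, δ₁<0 |
| I.tanh± | `−(h₂/h₃)(1 ± tanh(√h₂ξ/2))` | h₂>0, δ₁=0 |
| I.sech2 | `h₂ sech²(√h₂ξ/2)/(2√(h₂h₄) tanh(√h₂ξ/2) − h₃)` | h₂>0, h₂h₄≥0 |
| I.sec2 | `h₂ sec²(√−h₂ξ/2)/(−2√(−h₂h₄) tan(√−h₂ξ/2) − h₃)` | h₂<0, h₂h₄≤0 |
| II.sech / II.sec / II.rational | `√(−h₂/h₄) sech(√h₂ξ)` etc.; `1/(√h₄ξ)` | h₃=0 cases |
| III.sech2 / III.sec2 / III.rational | `−(h₂/h₃)sech²(√h₂ξ/2)` etc.; `4/(h₃ξ²)` | h₄=0 cases |

with `δ₁ = h₃² − 4h₂h₄`.  Note the rational degeneration of the h₄ = 0 case
is `4/(h₃ξ²)` — the prefactor 4 is required by the defining ODE.  Branch
preconditions are enforced with errors that name the violated inequality;
denominator zeros evaluate to NaN with a pole flag.  Further catalog cases
beyond these are out of scope.

## The two solution families

**Kink (Case II slice).**  On the slice `α₁ + β₁ = 0` — equivalently
`k₁ = 2/β₁² + 1` — the wave speed multiplies `(α₁+β₁)F′` and cancels from
the whole system, so `c` is genuinely free and must be supplied by the
user (the reference surfaces use `c = 1`, logged as such).  Solving the
system on this slice yields `λ = 2(β₁²+2)/(3β₁)`, `μ = 0` and
`k₂ = (4β₁⁴+7β₁²+16)/(9β₁²+18)`; at `β₁ = 0.5` these evaluate to
`λ = 3, k₁ = 9, k₂ = 8/9`.  The same slice is where Case I's speed formula
has its pole, so Case I is returned there with a validity-violation flag.

**Pulse (quartic, h₀ = 0).**  With the derived coefficients and `h₀ = 0`,
the I.sech2 catalog branch gives
`U = −β₁h₂ sech²(½√h₂ξ)/(2√(h₂h₄) tanh(½√h₂ξ) − h₃)`, `V = −U`.  The
branch identification is recorded in metadata as an inspection result.  The
denominator sweeps `(−2√(h₂h₄) − h₃, 2√(h₂h₄) − h₃)` as tanh runs over
(−1, 1), so the profile is pole-free whenever `|h₃| > 2√(h₂h₄)`; at the
reference parameters `(k₁, k₂, β₁) = (3, 0.5, 1)` the denominator stays in
(−7.16, −0.84).  Real coefficients require `h₄ ≥ 0`, i.e. `k₁ > 1` —
consistent with the admissibility condition; `k₁ < 1` requests are refused
with a complex-coefficient error.  Evaluators for `h₀ ≠ 0` are not built
(the coefficient derivation leaves h₀ free, but no catalog branch is wired
for it).

The pulse has `V = −U` exactly, so one of the densities is negative
wherever the other is positive.  The package does not resolve this
positivity question — sign violations are measured and reported
(`positivity_ok`, min-density fields) rather than branches being discarded.

## PDE simulator and verification

`verify_sim.pde_simulate` is a method-of-lines integrator: second-order
central differences for `V_XX`, zero-flux (mirror-ghost) boundaries —
chosen as the least-committal default since no boundary condition is
prescribed by the problem — and either forward Euler under the explicit
diffusion stability bound `dt ≤ 0.4·Δx²/2` (safety factor 0.4) or an
IMEX option (backward-Euler diffusion via a tridiagonal solve, explicit
reaction) for stiff runs.  Snapshot times are landed exactly by adjusting
the step per segment.  Fields exceeding 1e6 abort the run with a flag.

Correctness is checked by (a) stationarity of homogeneous equilibria over
T = 10 at 1e−10, (b) a manufactured solution `U* = e^(−t)sin x + 2`,
`V* = e^(−t)cos x + 2` on [0, π] (V* satisfies the zero-flux condition;
source terms are generated symbolically), whose observed spatial order must
lie in [1.8, 2.2] over nx ∈ {64, 128, 256}, and (c) a level-crossing
wave-speed estimator (linear interpolation of the single crossing per
snapshot, least-squares slope over time) that is exact on synthetic
translations and recovers the speed of a sampled closed-form kink to 1e−6.

The PDE comparison inside `verify_family` — a run initialized from a
closed-form profile, with the max divergence from the translated closed
form recorded at five times — is framed as a measurement, never a
pass/fail test, because the families solve only the combined ODE.

## Parameter studies

* Discriminant scan: Case I's `λ² − 4μ` over `k₁ ∈ (0,1) ∪ (1,10]` at fixed
  `(β₁, k₂) = (0.5, 0.5)` (defaults chosen as representative mid-range
  values; the scan is positive on both panels and diverges like
  `1/(k₁−1)²` approaching the degenerate point).
* Kink surfaces on the Case II slice at `β₁ = 0.5` (`c = 1` by default,
  with the free-parameter status logged).
* Pulse surfaces at `(k₁, k₂, β₁, c) = (3, 0.5, 1, 1)` on
  `x, t ∈ [−4, 4]`, with `max|U+V|` recorded (identically zero).

All study commands are deterministic: identical flags produce byte-identical
CSV.  Plots are optional, behind a flag; CSV is canonical so nothing in the
test-suite depends on rendering.

## Numerical-test conventions

Defining-ODE identities for the generator catalogs are checked with a
fourth-order central difference (step 3e−4) at sample points chosen away
from poles (the function and the whole stencil bounded), with residuals
normalized by the local size of the equation terms; the tolerance is 1e−9.
Symbolic identities are asserted exactly.  All randomized tests use fixed
seeds; hypothesis-based property tests run derandomized.

## Known limitations

* Only degree-(1,1) ansaetze are wired end-to-end; negative-power and
  higher-degree expansions are out of scope, as are other expansion schemes
  (tanh, Riccati, exp).
* Boundary-value solution of the travelling-wave ODEs (shooting or
  collocation) is not implemented; closed forms are the only profile
  source besides the PDE runs.
* The simulator is 1-D; no stochastic or time-delay variants.
* The families certify the combined ODE only; interpreting them as
  solutions of the original two-equation system is not supported by the
  residual measurements and is intentionally left open.
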