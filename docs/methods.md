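# Methods

## Model

We simulate a community of `p` organisms with biomasses `x ∈ R^p` growing on
a shared pool of `m` metabolites `y ∈ R^m` under a quasi-steady-state
assumption on internal metabolism: at every instant each organism's fluxes
solve its flux-balance problem, and the environment evolves by the exchange
fluxes that solution implies,

    dx_i/dt = x_i (γ_i · φ_i),        dy/dt = α − Σ_i x_i Γ*_i φ_i,

with per-organism LP

    max γ_i · φ    s.t.  A_i φ ≤ c_i(y, t),   Γ†_i φ = 0.

Notation. Exchange reactions in a GEM have standard-basis stoichiometry, so
the full stoichiometric matrix partitions as `Γ = [[I, −Γ*], [0, Γ†]]` with
external-metabolite rows on top; `ker Γ` is isomorphic to `ker Γ†` and the
exchange fluxes are the linear image `ψ = Γ* φ` of the internal ones.  We
use the uptake-positive sign convention for `ψ` (positive exchange flux
depletes the pool); models written secretion-positive are sign-flipped at
load time, and the flip recorded.  The inequality matrix is stacked in the
fixed block order `A = [Γ*; −Γ*; I; −I]` so that row indices — and hence
event logs — are reproducible; the right-hand side carries upper/lower
exchange bounds and internal flux bounds in matching order.  Steady-state
rows `Γ†` are kept as equalities and never folded into `A` as inequality
pairs, which keeps active-set ranks exact.  `α` is an optional constant
nutrient inflow, default zero (all shipped experiments use none).

Uptake bounds may be static or mass-action: `c²_ij(y) = κ_ij y_j`, the
simplest kinetics consistent with uptake ceasing on exhaustion.  Kinetic
detail beyond that (Michaelis–Menten saturation, regulation) is out of
scope.

## Basis tracking

Writing the LP in standard form `[Ã I](φ̃, s) = c`, `φ̃, s ≥ 0` (fluxes split
into positive/negative parts unless the system is natively nonnegative), a
bounded LP has a *basic* optimal solution `w = w_I(c)`: an index set `I` of
columns whose square submatrix `B_I` determines `w` by `B_I^{-1} c`.  While
`c(y, t)` drifts, `w_I(c(y, t))` remains the optimum until one of its
entries crosses zero — so between such events the simulation needs linear
algebra, not optimization.  We store the QR factors of the reduced `d × d`
system `B` (rows of `[A; Γ†]` tight at the optimum, `d` = number of internal
fluxes) and evaluate `φ(y, t) = B^{-1} c_J(y, t)` inside the integrator.

At an event the solution is degenerate: several basic index sets represent
the same optimum and most of them fail going forward (they track a point
that becomes infeasible or sub-optimal).  The forward-compatible basis is
chosen by the secondary LP

    max γ · φ̇   s.t.  a_j · φ̇ ≤ dc_j/dt  for each active inequality row,
                      Γ† φ̇ = 0,

whose constraints are exactly the first-order condition for the tracked
solution to remain feasible, and whose objective picks — among bases of the
given optimum, never among distinct optima — the one with the fastest
objective growth.  Choosing between distinct optimal flux vectors is a
biological question we deliberately do not answer.

Realization of the reduced basis.  The selected `J` must consist of `d`
linearly independent rows tight at the secondary optimum.  An optimizer may
return a face-interior point with fewer than `d` tight rows; we then slide
the solution along objective-neutral null directions (`z` with `T z = 0`,
`γ·z = 0`, ratio test against the remaining rows) until a vertex is reached
— the same effect as manually pivoting structural variables into a
degenerate basis.  Ties among eligible row subsets are broken
lexicographically by row index for cross-run reproducibility.

Treating `Γ†` rows as equalities in the secondary LP (rather than `≤ 0`
inequalities) is deliberate: a strictly negative `Γ† φ̇` would carry the
tracked solution off the steady-state manifold and force an event at the
very next step, defeating the method.  They remain eligible rows for `J`
with identically zero right-hand sides.

For the dynamic-bound rows, `dc²/dt = κ · ẏ` is the total derivative with
`ẏ` evaluated from the current community state (all organisms' tracked
fluxes).  This couples the basis choice of one organism to the others only
through `ẏ`, which is the physically meaningful rate.

## Event loop

Between events the right-hand side is smooth and is advanced with classic
fixed-step RK4; the method's accuracy claim concerns event handling, not
the smooth phase, so no adaptive stiff machinery is used.  After each step
every organism's tracked solution is checked against the full constraint
set.  On a violation, the first infeasibility time is localized by
bisection on the feasibility predicate (default tolerance `1e-9`), the
state reset there, and the violated rows appended to the active set before
re-solving the secondary LP.  When several organisms fail in one step they
are re-selected at the common earliest event time, preserving shared-pool
consistency; organisms that did not fail keep their bases.  If a freshly
selected basis is infeasible at `t + ε` (`ε = 1e-9·T`) with rows *not*
already in its constraint set, those rows are appended and the selection
retried (up to 5 times); if the violated rows are already present, the
basis is accepted — with event localization disabled the post-event basis
is legitimately infeasible until the true event time passes, and the next
step's check arbitrates.

Depletion events.  A statically-bounded nutrient reaching zero is a bound
discontinuity the LP cannot see through `c(y)`: the step size is halved
until the crossing is resolved (floor `1e-8·T`), the metabolite clamped at
zero, its uptake ceilings zeroed, and any organism whose tracked solution
violates the new bound re-selects its basis.  Mass-action bounds need none
of this: `κ y → 0` smoothly.

Tolerances (all configurable): active rows `|a·φ − c| ≤ 1e-7·(1+|c|)`
(relative scaling guards large-bound rows); feasibility `1e-8`; degeneracy
`1e-9`; optimality cross-checks `1e-6` relative.  Infinite bounds in source
models are replaced by `1e3` (logged) so standard form stays bounded; the
secondary LP additionally boxes `|φ̇| ≤ 1e6` and warns if the box binds,
since an under-constrained active set can leave it unbounded.

The LP backend is a bundled dense two-phase revised simplex with Bland's
rule.  Determinism of the reported basic index set is a correctness
requirement here, not a performance detail, which is why an external
solver is not in the loop; scipy's HiGHS serves as an independent
cross-check in the test suite only.  Problems are small (tens to a few
hundred rows), so dense refactorization per iteration is acceptable.

## Error behaviour

Between correctly-localized events the tracked solution is exact up to RK4
error.  An event localized only to within a step (localization disabled)
contributes a local error of first order in `Δt` when the flux vector is
discontinuous at the event — the depletion case — because the simulation
runs the wrong (pre-event) fluxes for an `O(Δt)` interval.  For gradual
basis switches under smoothly drifting bounds the old and new bases agree
at the event time, and the contribution is second order.  The shipped
convergence fixture (`ErrorOrderFixture`) therefore uses a depletion
event with a closed-form endpoint: a toy organism with growth rate
`μ = γ_eff φ*`, nutrient consumption `σ` per unit biomass, depletion time
`ln(1 + μ y₀/(σ x₀))/μ` and final biomass `x₀ + (μ/σ) y₀`.  Step sizes for
the study are chosen anti-resonant with the event (`Δt = t_event/(k+½)`)
so the event phase within its step is comparable across the curve; a
resonant grid would place the event exactly on step boundaries and measure
nothing.  The measured log-log slope is ≈ 1.0 without localization, and
localization reduces the error by 5–7 orders of magnitude at every step
size tested.

## Synthetic data

`make_toy_model(seed, m, d)` generates the study fixtures: a proportional
chain of `d` internal fluxes tied by `d−1` steady-state couplings, nutrient
`j` consumed by flux `j`, random positive coefficients, and either static
or mass-action uptake ceilings.  The construction guarantees a unique
non-degenerate growth optimum, an essential first nutrient, and (for the
static case) the closed forms above — so simulator output is checked
against pencil-and-paper solutions, not against itself.  Reference medium
is 10 concentration units per metabolite; community samplers draw
`κ_ij ~ U(0,1)` per the mass-action convention, with one RNG substream per
sample so enlarging a study never perturbs earlier draws.

What the toys do not emulate: genome-scale redundancy (thousands of
reactions with highly degenerate optima), secretion and cross-feeding,
reversible internal fluxes at the optimum, and numerically ill-scaled
stoichiometry.  Passing tests demonstrate the tracking, selection and
event machinery — including degenerate-optimum handling, which the toys
exercise through the worked LP and randomized degenerate instances — but
not performance or conditioning at genome scale; the download-gated
benchmark script exists for that.

## Known limitations

- Loss of *optimality* without loss of feasibility (an objective tie
  crossing) is not detected: like the underlying approach, events are
  defined by infeasibility of the tracked solution.
- The direct-Euler baseline uses a fixed step; adaptive ODE-suite baselines
  are out of scope, so cross-method counts are qualitative.
- No gene–protein–reaction rules, flux variability, loopless or
  thermodynamic constraints; no dilution/chemostat terms beyond the
  constant-inflow hook `α`.
- Fixed-step RK4 assumes the smooth phase is non-stiff, which holds for
  these ODEs away from events.
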