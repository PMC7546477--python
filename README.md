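# dfbasis — basis-reuse dynamic FBA for microbial communities

Dynamic flux balance analysis (dFBA) couples an ODE for biomasses `x_i` and a
shared metabolite pool `y` to a flux-balance linear program per organism:

```
dx_i/dt = x_i (γ_i · φ_i)                     φ_i = argmax γ_i · φ
dy_j/dt = − Σ_i x_i (Γ*_i φ_i)_j       s.t.   A_i φ ≤ c_i(y, t),  Γ†_i φ = 0
```

where `Γ*` maps internal fluxes `φ` to exchange fluxes `ψ = Γ* φ` (uptake
positive) and `Γ†` is the internal stoichiometry.  Tools that re-solve the LP
at every ODE step spend almost all of their time in the optimizer.  This
package instead tracks the *optimal basis*: a set `J` of `d` tight constraint
rows whose `d × d` system `B φ = c_J(y, t)` reproduces the LP optimum as
`(y, t)` drift.  The LP is only revisited when that tracked solution becomes
infeasible — and at that moment the optimum is degenerate (several bases
describe it), so the right basis to continue with is chosen by a small
*secondary* LP over the solution's time derivative:

```
max γ · φ̇    s.t.   a_j · φ̇ ≤ dc_j/dt   for every active row j
```

Among all bases of the current optimum this picks one that stays feasible
going forward and grows the objective fastest.  Between events the
simulation integrates a smooth linear-algebraic right-hand side (fixed-step
RK4 here) and is exact up to integrator error; events are localized by
bisection.  The result is orders of magnitude fewer LP solves than the
"static optimization approach" (a fresh solve per Euler step) at equal or
better accuracy.

Intended users: systems/computational biologists simulating metabolite-
mediated community dynamics from genome-scale metabolic models (GEMs), and
anyone studying parametric LP tracking.

## Worked example

The package ships a fully worked degenerate dynamic LP
(`dfbasis.make_example1()`):

```
max (1,1)·v   s.t.  v₁ ≤ 10,  v₂ ≤ 10,  v₁ + 2v₂ ≤ 30 − t,   v ≥ 0
```

```
$ dfbasis example1
optimal standard-form solution at t=0: [10. 10.  0.  0.  0.]
number of basic index sets for this optimum: 3
re-optimization at t = 20.000000 (violated: ['nonneg[phi_1]'])
optimizations: 2
```

At `t = 0` the optimum `v = (10, 10)` is degenerate: three bases describe it,
and only one of them — the one holding `v₁ ≤ 10` and the shrinking mixed row
tight, with tracked solution `(10, 10 − t/2)` — solves the dynamic problem.
The tracker selects it from the secondary LP, follows it without a single
re-solve for twenty time units, localizes the event where `v₂` would go
negative at `t = 20.000000`, and switches basis once.  Two optimizations
total; a direct method at `Δt = 0.05` would have used 500.

The same machinery on a two-organism synthetic community with mass-action
uptake bounds (`κ_ij · y_j`):

```python
import dfbasis as dfb

models, bounds, medium = dfb.make_toy_community(7, 2, 2, 2, uptake="linear")
rep = dfb.compare_methods(models, medium, [0.3, 0.3], 2.0, dt=0.1, bounds=bounds)
print(rep.counts)
# {'basis_reuse': {'org0': 2, 'org1': 1, 'total': 3},
#  'direct_euler': {'org0': 20, 'org1': 20, 'total': 40}}
```

Three LP solves instead of forty: one initial solve per organism plus a
single re-selection for `org0` at `t ≈ 0.543`, when its uptake ceiling on
`met1` becomes binding as the nutrient runs down.

CLI verbs: `simulate`, `compare`, `sample` (Monte-Carlo over uptake rates
`κ`), `example1`.  Inputs are SBML-FBC or JSON GEMs, a medium CSV
(`metabolite_id,concentration`) and an optional κ CSV; outputs are TSV
timecourses, JSON event logs and CSV outcome tables.  See
`docs/methods.md` for the method, assumptions and numerical choices.

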