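# scgma

Exact recasting of Saturable-and-Cooperative (SC) kinetic models into
Generalized Mass Action (GMA) canonical form, and certified deterministic
global optimization of the recast steady-state enzyme-modulation problem.

## The problem

Metabolic engineering asks: given a kinetic model of a pathway, which
fold-changes in enzyme activities maximize a target concentration or flux at
the new steady state, subject to physiological bounds?  Realistic rate laws
make this a nonconvex problem that local solvers cannot certify.

This package works with networks whose node dynamics are

```
dX_i/dt = Σ_r μ_ir k_r v_r ,
v_r = V_r Π_j X_j^{n_rj} / Π_j (K_rj + X_j^{n_rj})        (SC rate law)
```

where `k_r` is a dimensionless enzyme-activity multiplier (1 at the basal
state), `n_rj` are real kinetic orders (negative for inhibition), and
`K_rj > 0` half-saturation constants.  Introducing one auxiliary variable
`z_rj = K_rj + X_j^{n_rj}` per denominator factor rewrites every rate as a
single power-law monomial `V_r k_r Π X^n Π z^{-1}` and — after expanding the
chain rule — every ODE as a signed sum of monomials: an **exactly
equivalent** GMA model (same trajectories, same steady states).  General
rational rate laws (e.g. Michaelis–Menten with competitive inhibition) recast
the same way, one `z` per signomial denominator factor.

On the recast form, the steady-state design problem

```
max  X_i or v_r
s.t. Σ_r μ_ir k_r V_r Π X^n Π z^{-1} = 0          (balances)
     K_rj + X_j^{n_rj} = z_rj                      (links)
     X^L ≤ X ≤ X^U,  k^L ≤ k ≤ k^U,  flux bands, cardinality limits
```

is solved to a certified relative optimality gap by a deterministic spatial
branch-and-bound: the substitution `y=ln X, w=ln z, u=ln k` turns every
monomial into `exp(affine)`, bounded above and below by secant and tangent
(outer-approximation) cuts in small LPs, with saturation cuts `w ≥ n·y`
(every saturable fraction lies below 1), interval bound tightening, and
incumbents generated through the network's actual steady states — so every
reported solution is feasible for the *original* model by construction.

## Worked example

```python
import scgma

net   = scgma.model_a()            # branched 4-metabolite reference network
gma   = scgma.recast_sc(net)       # 8 auxiliary variables, 12 dynamic variables
basal = scgma.basal_state(net)     # X = (1,1,1,1), v = (10,10,6,6,4,4)

scen    = scgma.scenario("O1", "v4")          # 0.2 ≤ k ≤ 5, 0.1 ≤ X ≤ 10
problem = scgma.build_problem(gma, scen, basal=basal)
sol     = scgma.solve_global(problem)

print(sol.objective_value, sol.bound, sol.gap, sol.status)
# 37.47036619029777 37.47036619029777 0.0 optimal-to-tolerance
print({r: round(k, 3) for r, k in sol.k.items()})
# {'v1': 4.005, 'v2': 4.249, 'v3': 5.0, 'v4': 5.0, 'v5': 0.2, 'v6': 0.359}
```

The certified optimum 37.47 equals the analytic supply cap of the
`X2 → X3` step, `7.5·5·X2^2.5/(X2^2.5+0.25)` at `X2 = 10`.  The optimal
enzyme profile is degenerate (a whole region attains 37.47 — see
`enumerate_equivalent_optima`), so profiles may differ between runs of
different algorithms while the objective value is stable.

The same pipeline with `scenario("O2", ...)` (metabolites within 10% of
basal), `"O3"` (output flux within 10% of basal), `"O4"` (at most three
enzymes manipulated; solved by subset enumeration), and `"O5"` (the
steep-kinetics hard instance on `scgma.model_b()`) reproduces the full
reference study; `scgma.grid_study` yields the cell-wise optima when two
enzymes are confined to a grid.

A command line mirrors the library:

```
scgma simulate  --model A --x0 2,1,1,1 --horizon 100 --out traj.tsv
scgma recast    --model A --out model_a_gma.yaml
scgma optimize  --model A --scenario O1 --objective v4 --tol 0.002
scgma grid      --model A --objective v4 --vars v2,v5 --ranges 4:5,0.2:0.8 --bins 8,8
scgma reproduce --table 2 --out-dir out/
scgma validate  model_a.yaml
```

`optimize` exits 0 when the solve certifies to tolerance and 3 when only a
bound is available.

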