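# Methods

## Model classes

A `ReactionNetwork` couples signed stoichiometry `μ_ir` with per-reaction
rate laws over strictly positive concentrations (arbitrary units; the whole
package is dimensionless).  Three families are supported:

* **SC (Saturable and Cooperative)**: `v = V Π_j X_j^{n_j} / Π_j (K_j + X_j^{n_j})`
  with real nonzero kinetic orders (negative = inhibition) and positive
  half-saturation constants.  The local power-law picture translates into SC
  parameters via `n_j = f_j/(1−p_j)` and `K_j = ((1−p_j)/p_j)·X_{j0}^{n_j}`,
  where `p_j ∈ (0,1)` is the saturation fraction at the operating point, and
  the limit rate is fixed by the operating flux (`powerlaw_to_sc`).
* **Rational**: a positive monomial numerator over a product of signomial
  denominator factors with positive coefficients (covers Michaelis–Menten
  with competitive inhibition, Hill forms, and every SC law).
* **Power law**: a single monomial (no denominator, no auxiliary variable on
  recasting).

Zero concentrations are rejected rather than limiting-cased: all machinery
(recasting, log-space solving) lives on the open positive orthant.

## Exact recasting

One auxiliary variable is introduced per denominator factor,
`z = factor(X)`; each rate becomes the monomial `V k Π X^n Π z^{-1}`, and the
auxiliary ODEs follow by the chain rule with the metabolite derivatives
substituted by their own monomial sums, so the emitted model is syntactically
GMA (the downstream optimizer consumes monomial sums only).  Auxiliary
variables are named `z_<reaction>_<variable>` (SC factors) or
`z_<reaction>_f<i>` (general factors) and ordered by (reaction, factor), so
recasting is reproducible and diffable.  Exponent arithmetic drops `X^0`
factors symbolically; like terms are merged by exponent signature.

The transformation is exact, not approximate: with link-consistent initial
conditions `z(0) = factor(X(0))` the recast trajectories coincide with the
original ones, and the link identity is a conserved invariant of the recast
ODEs.  The test suite checks both on the two case-study models, the rational
chain fixture, and twenty generated random networks; the acceptance bar of
1e−6 maximum relative deviation is our choice, tied to the integrator
tolerances (the equivalence itself is exact in exact arithmetic).

## Dynamics and steady states

Simulation uses a stiff-capable integrator (LSODA; the auxiliary ODEs can be
stiff near saturation) at default tolerances rel 1e−9 / abs 1e−11 for
equivalence work.  Steady states are found by damped root finding on the
node equations in log space (unknowns `ln X`, which enforces positivity
without constraints), falling back to integrating towards equilibrium and
polishing the endpoint; equilibrium detection uses
`‖Ẋ‖_∞ < 1e−10·(1+‖X‖_∞)`.  The basal state is the steady state at all
`k_r = 1` and anchors every relative constraint.

Two values the source material leaves unstated are reconstructed here and
are configuration-overridable: the fixed source concentration is `X5 = 1`
for the reference branched model (the only value at which its printed
parameters balance at X = (1,1,1,1) with fluxes (10,10,6,6,4,4)) and
`X5 = 2` for the steep-kinetics variant (the only value at which the
published optimal profile is flux-consistent).  These are reconstructions,
not published facts.  The rational-chain fixture is published in symbolic
form only; the built-in numeric defaults (V1=10, K1=Ki=1, V2=8, K2=1, V3=12,
K3=1, source X3=2) are this package's choice and place a stable positive
equilibrium near X = (1.43, 0.80); its recasting structure is checked
symbolically against the hand-derived auxiliary ODEs, independent of those
numbers.

## Global optimization

The steady-state design problem is solved on the recast form.  After
`y = ln X, w = ln z, u = ln k`, balances are signed sums of `exp(affine)`
terms and links read `e^w = K + e^{n·y}`.  Flux bands and single-monomial
objectives are *linear* in the transformed variables, which the solver
exploits directly.

Bounding uses small dense LPs (HiGHS via scipy): each distinct exponential
term gets an LP variable tied to its affine exponent by tangent
(under-estimating) and secant (over-estimating) cuts over the current box,
with extra tangents added at the LP solution for a few rounds.  Two
structural ingredients matter most for tight root relaxations:

* **Saturation cuts** `w ≥ ln c + a·y` for every monomial of every link
  definition — pointwise encodings of `z ≥ K` and `z ≥ X^n`, i.e. every
  saturable fraction lies below 1.  These reproduce analytic flux caps
  (e.g. the 37.47 supply cap of the reference model) already in the root LP.
* **Grouped term intervals**: a rate term's range is computed with each
  matched fraction `X^n/(K + X^n)` evaluated jointly over the `y` box
  (it lies in (0,1) and is monotone in `X^n`), rather than treating `y` and
  `w` as independent intervals.

Around the LP sit feasibility-based bound tightening (exact `w` ranges from
the links, interval propagation through balance/link equalities and all
linear rows) and optimality-based bound tightening (per-variable min/max
LPs with an incumbent cutoff row) at the root and periodically at the
bound-defining node.  Branching acts on metabolite and enzyme variables
only — auxiliary bounds always follow from the links — choosing the variable
with the largest violation-weighted width, splitting at the LP point clamped
to the central half of the box.

Incumbents never come from the relaxation: candidate enzyme profiles (from
LP points, deterministic multistarts, and SLSQP polishing over `ln k` with
steady-state-implicit constraints) are evaluated by actually solving the
network's steady state, so every reported solution is feasible for the
original nonlinear model with slack ≥ −1e−8.  The search is deterministic;
seeded randomness exists only in the equivalent-optima enumeration and the
random-network generator.  Termination: relative gap ≤ tol (default 0.2%,
matching the reference study; 2% for the hard instance), or node/time
limits with status `bound-only`.

**Cardinality limit** (at most `ME` enzymes outside an unchanged band
`[1−δ, 1+δ]`): solved by enumerating all size-`ME` subsets of movable
enzymes, boxing the rest to the band and sharing the incumbent across
subsets as a cutoff; the certified bound is the maximum over subsets.  The
default `δ = 0.001` pins unmanipulated enzymes to basal activity: the
reference optima hold them at exactly 1.00, and any appreciably wider band
would let the optimizer park "unchanged" enzymes at the band edges and
overshoot the published optimum (with δ = 0.05 the true optimum of the
`ME=3` flux task is 8.38, not 7.61).  δ remains a parameter.

**Hard instance**: under the printed bounds (k ≤ 20, X4 ≤ 50) the certified
optimum of the steep-kinetics model is v6 = 133.0, attained at the flux cap
`6.67·20·X4^{1.57}/(X4^{1.57}+1.40)` with X4 = 50; the corresponding steady
state was verified independently by re-solving the original ODE system and
checking every node balance.  This exceeds the historically reported best
feasible value (60.46, from solvers that stalled on this instance), which
the package therefore treats as a lower target to match or exceed.

**Equivalent optima**: the reference problems are degenerate in `k`
(regions of profiles share one objective value).  `enumerate_equivalent_optima`
re-optimizes secondary linear objectives over `ln k` (coordinate directions
first, then seeded random directions) under a near-optimality constraint and
deduplicates profiles within a log-space radius.

**Brute-force oracle**: an independent validation path — a dense grid over
the enzyme box evaluated through steady-state simulation only, no recast
algebra or relaxations — used in tests on two-control restrictions of the
reference problems, where the two routes agree to well below 0.5%.

## Random network generator

Property tests draw connected branched SC networks from a seeded generator:
a source → chain → sink backbone plus random conversions/exits, fluxes
assigned by forward balancing so the all-ones state is an exact steady state
(residual < 1e−8 by construction), at least one inhibitory modifier forced,
kinetic orders and half-constants uniform on configurable ranges (defaults
0.5–3 and 0.1–2, the magnitude range of the case-study models).  The
generator emulates the structural features the recasting and solver rely on
— branching, feedback inhibition, saturable steps with a known operating
point — and deliberately not other features of real data (no conservation
moieties, no reversible rate laws, no multi-substrate kinetics, no noise),
so passing tests demonstrate exactness and certification on this model
class, not biological fidelity of any particular network.

## Problem sizes and runtimes

All reference computations are desk scale: 4 metabolites + 8 auxiliaries +
6 controls (18 unknowns) for the branched model, identical counts for the
steep variant.  On one CPU the continuous scenarios certify in roughly 2–10 s
each, the cardinality tasks (20 subsets) in ~20 s, the full 8×8 grid study
(64 certified cell solves) in ~4 min, and the hard instance in ~15 s; the
acceptance script completes in a few minutes.

## Known limitations

* Recasting requires signomial denominator factors that stay positive on the
  admissible box; transcendental rate laws (exponentials, logarithms) are out
  of scope.
* The steady-state map `k → X(k)` used for incumbents returns one equilibrium
  per profile (from warm/basal/unit starts plus a relaxation fallback); on
  models with multiple coexisting equilibria the incumbent side may explore
  only one branch, though the certified bound is unaffected.
* Cardinality enumeration scales as `C(p, ME)`; fine for single-digit enzyme
  counts, not for genome-scale models.
* The branch-and-bound certifies maximization of a single concentration or
  flux; multi-objective formulations are not implemented.
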