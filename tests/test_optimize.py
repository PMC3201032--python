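"""Problem construction and solver behaviour on quick instances.

The full reference reproductions live in test_acceptance; here the focus is
on contracts: constraint instantiation, feasibility of incumbents, the
cardinality reduction, the midpoint oracle, and equivalent-optima plumbing.
"""

import math

import numpy as np
import pytest

import scgma
from scgma import (
    ParameterError,
    Scenario,
    brute_force_oracle,
    build_problem,
    enumerate_equivalent_optima,
    scenario,
    solve_global,
    solve_with_cardinality,
)


def test_scenario_factory_validation():
    with pytest.raises(ParameterError):
        scenario("O9", "X3")
    with pytest.raises(ParameterError):
        scenario("O1")  # objective required
    with pytest.raises(ParameterError):
        Scenario(name="bad", objective="X3", tol=0.5)
    with pytest.raises(ParameterError):
        Scenario(name="bad", objective="X3", cardinality=(0, 0.05))


def test_o1_problem_boxes(gma_a, basal_a):
    prob = build_problem(gma_a, scenario("O1", "X3"), basal=basal_a)
    assert prob.system.n_balance == 4
    assert prob.system.n_link == 8
    assert all(b == (0.2, 5.0) for _, b in prob.k_bounds)
    assert all(b == (0.1, 10.0) for _, b in prob.x_bounds)
    assert prob.flux_bounds == ()


def test_o2_problem_boxes_relative_to_basal(gma_a, basal_a):
    prob = build_problem(gma_a, scenario("O2", "v4"), basal=basal_a)
    assert prob.x_bounds_dict == pytest.approx(
        {v: (0.9, 1.1) for v in gma_a.dependent})


def test_o3_problem_has_flux_band(gma_a, basal_a):
    prob = build_problem(gma_a, scenario("O3", "X3"), basal=basal_a)
    assert prob.flux_bounds_dict["v4"] == pytest.approx((5.4, 6.6))


def test_relative_bounds_require_basal(gma_a):
    with pytest.raises(ParameterError, match="basal"):
        build_problem(gma_a, scenario("O2", "X3"))


def test_unknown_objective_rejected(gma_a, basal_a):
    with pytest.raises(ParameterError):
        build_problem(gma_a, scenario("O1", "X9"), basal=basal_a)


def test_solve_with_pinned_enzymes_reproduces_published_profile(gma_a, basal_a):
    """Fixing k at a published optimal profile and solving only the steady
    state must reproduce the published objective (feasibility cross-check)."""
    prob = build_problem(gma_a, scenario("O1", "X3"), basal=basal_a)
    pinned = {"v1": 0.26, "v2": 5.0, "v3": 5.0, "v4": 0.2, "v5": 0.2, "v6": 0.2}
    prob = prob.with_k_bounds({r: (k, k) for r, k in pinned.items()})
    sol = solve_global(prob, time_limit=60.0)
    assert sol.objective_value == pytest.approx(8.30, rel=0.005)


def test_incumbent_is_steady_and_within_bounds(net_a, gma_a, basal_a):
    prob = build_problem(gma_a, scenario("O2", "X3"), basal=basal_a)
    sol = solve_global(prob, time_limit=60.0)
    assert sol.certified
    res = scgma.find_steady_state(net_a, k=sol.k)
    assert res.residual < 1e-8
    for v, (lo, hi) in prob.x_bounds:
        assert lo - 1e-8 <= res.state[v] <= hi + 1e-8
    # the reported state matches an independent re-solve
    for v in net_a.dependent:
        assert sol.state[v] == pytest.approx(res.state[v], abs=1e-7)


def test_bound_sandwich(gma_a, basal_a):
    prob = build_problem(gma_a, scenario("O2", "v4"), basal=basal_a)
    sol = solve_global(prob, time_limit=60.0)
    assert sol.objective_value <= sol.bound * (1 + 1e-9)
    assert sol.gap >= 0.0


def test_cardinality_with_full_support_matches_unrestricted(gma_a, basal_a):
    """ME = p lets every enzyme move: the optimum equals the O2 optimum."""
    scen = Scenario(name="O4-full", objective="X3", k_bounds=(0.2, 5.0),
                    x_bounds=None, x_rel_band=(0.9, 1.1),
                    cardinality=(6, 0.001))
    prob = build_problem(gma_a, scen, basal=basal_a)
    sol = solve_with_cardinality(prob, time_limit=120.0)
    ref = solve_global(build_problem(gma_a, scenario("O2", "X3"), basal=basal_a),
                       time_limit=60.0)
    assert sol.objective_value == pytest.approx(ref.objective_value, rel=0.005)


def test_oracle_midpoint_mode(gma_a, basal_a):
    res = brute_force_oracle(gma_a, scenario("O2", "X3"), grid_per_dim=1,
                             basal=basal_a)
    assert res.n_evaluated == 1
    # midpoint of [0.2, 5] on every enzyme scales all rates equally, which
    # leaves the basal concentrations unchanged
    assert res.objective_value == pytest.approx(1.0, rel=1e-6)


def test_oracle_grid_size_guard(gma_a, basal_a):
    with pytest.raises(ParameterError):
        brute_force_oracle(gma_a, scenario("O1", "X3"), grid_per_dim=11,
                           basal=basal_a)


def test_equivalent_optima_on_degenerate_objective(gma_a, basal_a):
    """The O1-v4 optimum is attained on a whole region of enzyme profiles."""
    prob = build_problem(gma_a, scenario("O1", "v4"), basal=basal_a)
    sols = enumerate_equivalent_optima(prob, of_star=37.47, tol=0.002,
                                       count=4, seed=11)
    assert len(sols) >= 2
    for s in sols:
        assert s.objective_value >= 0.998 * 37.47 - 1e-9
        res = scgma.find_steady_state(prob.gma.source, k=s.k)
        assert res.residual < 1e-8
    # pairwise distinct beyond the declared radius
    ks = [np.log([s.k[r] for r in prob.gma.source.reaction_ids]) for s in sols]
    for i in range(len(ks)):
        for j in range(i + 1, len(ks)):
            assert np.max(np.abs(ks[i] - ks[j])) > 0.05


def test_grid_study_restriction_monotonicity(gma_a, basal_a, solutions):
    """Any cell optimum is bounded by the unrestricted optimum."""
    prob = build_problem(gma_a, scenario("O1", "v4"), basal=basal_a)
    res = scgma.grid_study(prob, "v2", (4.0, 5.0), 2, "v5", (0.2, 0.8), 2,
                           cells=[(0, 0), (1, 1)], time_limit_per_cell=60.0)
    unrestricted = solutions.get("O1", "v4").objective_value
    vals = res.values[np.isfinite(res.values)]
    assert vals.size == 2
    assert np.all(vals <= unrestricted * (1 + 1e-6))
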