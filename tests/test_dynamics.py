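"""Simulation, steady-state solving, basal states, equivalence reports."""

import numpy as np
import pytest

from scgma import (
    DomainError,
    basal_state,
    equivalence_report,
    find_steady_state,
    simulate,
)


def test_basal_start_gives_constant_trajectory(net_a):
    traj = simulate(net_a, [1.0, 1.0, 1.0, 1.0], 50.0)
    assert np.max(np.abs(traj.values - 1.0)) < 1e-8
    assert np.all(np.diff(traj.t) > 0)


def test_perturbed_start_relaxes_to_basal(net_a):
    traj = simulate(net_a, [2.0, 1.0, 1.0, 1.0], 100.0)
    assert traj.final_state() == pytest.approx(
        {"X1": 1.0, "X2": 1.0, "X3": 1.0, "X4": 1.0}, abs=1e-6)


def test_integrator_tolerance_convergence(net_a):
    """Tightening tolerances changes the answer by less than the looser one."""
    loose = simulate(net_a, [2.0, 1.0, 1.0, 1.0], 50.0, rel_tol=1e-7, abs_tol=1e-9)
    tight = simulate(net_a, [2.0, 1.0, 1.0, 1.0], 50.0, rel_tol=1e-10, abs_tol=1e-12)
    assert np.max(np.abs(loose.values - tight.values)) < 1e-5


def test_simulation_rejects_bad_initial_state(net_a):
    with pytest.raises(DomainError):
        simulate(net_a, [0.0, 1.0, 1.0, 1.0], 10.0)
    with pytest.raises(ValueError):
        simulate(net_a, [1.0, 1.0, 1.0, 1.0], -5.0)


def test_steady_state_from_far_guess(net_a):
    res = find_steady_state(net_a, guess=[5.0, 5.0, 5.0, 5.0])
    assert res.state == pytest.approx(
        {"X1": 1.0, "X2": 1.0, "X3": 1.0, "X4": 1.0}, abs=1e-9)
    assert res.fluxes == pytest.approx(
        {"v1": 10.0, "v2": 10.0, "v3": 6.0, "v4": 6.0, "v5": 4.0, "v6": 4.0}, abs=1e-8)
    assert res.residual < 1e-9


def test_steady_state_solve_is_idempotent(net_a):
    first = find_steady_state(net_a, k={"v2": 1.7, "v5": 0.6})
    again = find_steady_state(net_a, k={"v2": 1.7, "v5": 0.6},
                              guess=first.state)
    for v in net_a.dependent:
        assert again.state[v] == pytest.approx(first.state[v], abs=1e-12)


@pytest.mark.parametrize("k", [None, {"v4": 2.0}, {"v2": 1.5, "v6": 0.7}])
def test_steady_state_flux_pattern(net_a, k):
    """Branched topology: v1 = v2, v2 = v3 + v5, v3 = v4, v5 = v6."""
    res = find_steady_state(net_a, k=k)
    f = res.fluxes
    assert f["v1"] == pytest.approx(f["v2"], abs=1e-8)
    assert f["v2"] == pytest.approx(f["v3"] + f["v5"], abs=1e-8)
    assert f["v3"] == pytest.approx(f["v4"], abs=1e-8)
    assert f["v5"] == pytest.approx(f["v6"], abs=1e-8)


def test_basal_state_of_model_a(net_a):
    bas = basal_state(net_a)
    assert bas.concentrations == pytest.approx(
        {"X1": 1.0, "X2": 1.0, "X3": 1.0, "X4": 1.0}, abs=1e-9)
    assert bas.fluxes["v4"] == pytest.approx(6.0, abs=1e-9)
    assert bas.residual < 1e-10


def test_basal_state_of_model_b_exists(net_b):
    bas = basal_state(net_b)
    assert bas.residual < 1e-8
    assert all(x > 0 for x in bas.concentrations.values())


def test_recast_trajectory_matches_original(net_a, gma_a):
    rep = equivalence_report(net_a, gma_a, [2.0, 1.0, 1.0, 1.0], 60.0)
    assert rep.max_rel_overall < 1e-6
    assert rep.max_link_drift < 1e-6


def test_corrupted_aux_start_is_flagged(net_a, gma_a):
    rep = equivalence_report(net_a, gma_a, [2.0, 1.0, 1.0, 1.0], 5.0,
                             z0={"z_v4_X3": 3.5})  # true link value is 2.0
    assert rep.link_drift["z_v4_X3"] > 0.1


def test_gma_steady_state_includes_link_consistent_aux(net_a, gma_a):
    res = find_steady_state(gma_a, k={"v3": 1.3})
    for aux in gma_a.aux:
        full = {**gma_a.independent_dict,
                **{v: res.state[v] for v in gma_a.dependent}}
        assert res.state[aux.name] == pytest.approx(aux.definition.value(full), rel=1e-12)
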