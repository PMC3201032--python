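"""Network data model, built-in fixtures, and the random SC generator."""

import numpy as np
import pytest

from scgma import (
    ParameterError,
    ReactionNetwork,
    SCRateLaw,
    builtin_models,
    generate_random_sc,
    model_a,
    model_b,
    node_derivatives,
)


def test_model_a_shape():
    net = model_a()
    assert len(net.dependent) == 4
    assert len(net.independent) == 1
    assert len(net.reactions) == 6
    n_orders = sum(len(law.kinetic_orders) for _, law in net.reactions)
    assert n_orders == 8


def test_model_b_v2_parameters():
    law = model_b().rate_laws["v2"]
    assert law.orders_dict == {"X1": 1.54, "X3": -6.81}
    assert law.half_dict == {"X1": 0.61, "X3": 0.11}


def test_model_a_stoichiometry_row_for_x2():
    stoich = model_a().stoich_dict
    row = {rid: mu["X2"] for rid, mu in stoich.items() if "X2" in mu}
    assert row == {"v2": 1.0, "v3": -1.0, "v5": -1.0}


def test_builtin_models_returns_three_fixtures():
    models = builtin_models()
    assert set(models) == {"A", "B", "MM"}
    assert models["A"].independent_dict == {"X5": 1.0}
    assert models["B"].independent_dict == {"X5": 2.0}


def test_unit_state_is_a_steady_state_of_model_a():
    net = model_a()
    state = {v: 1.0 for v in net.dependent}
    assert net.fluxes(state) == pytest.approx(
        {"v1": 10.0, "v2": 10.0, "v3": 6.0, "v4": 6.0, "v5": 4.0, "v6": 4.0})
    derivs = node_derivatives(net, state)
    assert all(abs(d) < 1e-12 for d in derivs.values())
    assert derivs["X5"] == 0.0  # independent variables do not move


def test_zero_enzyme_activity_freezes_the_network():
    net = model_a()
    state = {"X1": 2.0, "X2": 0.5, "X3": 1.3, "X4": 0.8}
    k = {rid: 0.0 for rid in net.reaction_ids}
    assert all(d == 0.0 for d in node_derivatives(net, state, k).values())


@pytest.mark.parametrize("rid", ["v1", "v3", "v5"])
def test_node_derivatives_linear_in_each_enzyme(rid):
    """Doubling one k_r doubles exactly that reaction's contribution."""
    net = model_a()
    state = {"X1": 1.4, "X2": 0.7, "X3": 1.9, "X4": 1.1}
    k1 = {r: 1.0 for r in net.reaction_ids}
    k2 = dict(k1, **{rid: 2.0})
    d1 = node_derivatives(net, state, k1)
    d2 = node_derivatives(net, state, k2)
    v = net.fluxes(state, k1)[rid]
    mu = net.stoich_dict[rid]
    for var in net.dependent:
        assert d2[var] - d1[var] == pytest.approx(mu.get(var, 0.0) * v, abs=1e-12)


def test_independent_override():
    net = model_a().with_independent({"X5": 2.0})
    assert net.independent_dict == {"X5": 2.0}
    with pytest.raises(ParameterError):
        model_a().with_independent({"X1": 2.0})


def test_network_validation_rejects_inconsistencies():
    law = SCRateLaw.make(1.0, {"X1": 1.0}, {"X1": 1.0})
    with pytest.raises(ParameterError, match="unknown reaction"):
        ReactionNetwork.make("bad", ["X1"], {}, {"v1": law}, {"v9": {"X1": 1.0}})
    ghost = SCRateLaw.make(1.0, {"X9": 1.0}, {"X9": 1.0})
    with pytest.raises(ParameterError, match="undeclared"):
        ReactionNetwork.make("bad", ["X1"], {}, {"v1": ghost}, {"v1": {"X1": 1.0}})


def test_generator_is_deterministic_per_seed():
    m1 = generate_random_sc(7, n_vars=3, n_reactions=5)
    m2 = generate_random_sc(7, n_vars=3, n_reactions=5)
    assert m1 == m2
    m3 = generate_random_sc(8, n_vars=3, n_reactions=5)
    assert m1 != m3


@pytest.mark.parametrize("seed", range(6))
def test_generated_models_balance_at_the_unit_state(seed):
    net = generate_random_sc(seed, n_vars=4, n_reactions=7)
    state = {v: 1.0 for v in net.dependent}
    derivs = node_derivatives(net, state)
    assert max(abs(d) for d in derivs.values()) < 1e-8


def test_generated_models_contain_an_inhibitor():
    for seed in range(6):
        net = generate_random_sc(seed, n_vars=4, n_reactions=7)
        orders = [e for _, law in net.reactions for e in law.orders_dict.values()]
        assert any(e < 0 for e in orders)


def test_generator_with_unit_orders_gives_mm_shaped_factors():
    net = generate_random_sc(3, n_vars=2, n_reactions=4, order_range=(1.0, 1.0))
    for _, law in net.reactions:
        for e in law.orders_dict.values():
            assert abs(e) == pytest.approx(1.0)


def test_generator_rejects_infeasible_requests():
    with pytest.raises(ParameterError):
        generate_random_sc(0, n_vars=0, n_reactions=3)
    with pytest.raises(ParameterError):
        generate_random_sc(0, n_vars=4, n_reactions=3)  # fewer than chain needs
    with pytest.raises(ParameterError):
        generate_random_sc(0, n_vars=2, n_reactions=4, K_range=(-1.0, 2.0))
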