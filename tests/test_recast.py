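"""Recasting into GMA canonical form: structure, links, steady-state system."""

import numpy as np
import pytest

from scgma import (
    DomainError,
    Monomial,
    ParameterError,
    RecastTypeError,
    SCRateLaw,
    ReactionNetwork,
    initial_aux_state,
    mm_chain,
    model_a,
    recast_rational,
    recast_sc,
    steady_state_system,
)


def _terms_as_set(monos):
    return {(round(m.coeff, 10), m.powers, m.k_powers) for m in monos}


def test_model_a_recast_counts(gma_a):
    assert len(gma_a.aux) == 8          # one z per nonzero kinetic order
    assert len(gma_a.variables) == 12   # 4 metabolites + 8 auxiliaries
    assert gma_a.aux_names == (
        "z_v1_X5", "z_v2_X1", "z_v2_X3", "z_v3_X2",
        "z_v4_X3", "z_v5_X1", "z_v5_X2", "z_v6_X4")


def test_v4_recast_structure(gma_a):
    # v4 = 12 k4 X3 / (X3 + 1):  z = 1 + X3, rate 12 k4 X3 z^-1, zdot = v3 - v4
    aux = gma_a.aux_by_name("z_v4_X3")
    assert _terms_as_set(aux.definition.terms) == {
        (1.0, (), ()), (1.0, (("X3", 1.0),), ())}
    rate = gma_a.rates_dict["v4"]
    assert rate.coeff == pytest.approx(12.0)
    assert rate.powers_dict == {"X3": 1.0, "z_v4_X3": -1.0}
    assert rate.k_powers_dict == {"v4": 1.0}
    v3 = gma_a.rates_dict["v3"]
    assert _terms_as_set(aux.ode) == _terms_as_set([v3, rate.scaled(-1.0)])


def test_every_recast_ode_is_monomial(gma_a):
    for var, terms in gma_a.x_odes_dict.items():
        assert len(terms) >= 1
    for var, terms in gma_a.odes.items():
        # the auxiliary tied to the fixed source variable is constant (empty ODE)
        for m in terms:
            assert isinstance(m, Monomial)
            assert m.coeff != 0.0
    assert gma_a.z_odes_dict["z_v1_X5"] == ()


def test_recast_sc_rejects_rational_laws():
    with pytest.raises(RecastTypeError, match="recast_rational"):
        recast_sc(mm_chain())


def test_sc_law_with_zero_half_constant_is_rejected():
    with pytest.raises(ParameterError):
        SCRateLaw.make(12.0, {"X3": 1.0}, {"X3": 0.0})


def test_recast_rational_on_sc_model_matches_recast_sc(net_a, gma_a):
    via_rational = recast_rational(net_a)
    assert via_rational.aux_names == gma_a.aux_names
    assert via_rational.rates == gma_a.rates
    assert via_rational.x_odes == gma_a.x_odes
    assert {a.name: a.ode for a in via_rational.aux} == {a.name: a.ode for a in gma_a.aux}


def test_pure_powerlaw_rate_gains_no_auxiliary():
    from scgma import PowerLawRate
    net = ReactionNetwork.make(
        "pl", ["X1"], {"X0": 1.0},
        {"v1": PowerLawRate.make(2.0, {"X0": 1.0}),
         "v2": PowerLawRate.make(2.0, {"X1": 0.5})},
        {"v1": {"X1": 1.0}, "v2": {"X1": -1.0}})
    gma = recast_rational(net)
    assert gma.aux == ()
    assert gma.rates_dict["v2"].powers_dict == {"X1": 0.5}


def test_mm_chain_aux_definitions(gma_mm):
    """The worked rational example: z1 = K1(1 + Ki/X2) + X3, z2 = K2 + X1,
    z3 = K3^2 + X2^2 (defaults K1=K2=K3=Ki=1, X3 fixed)."""
    z1 = gma_mm.aux_by_name("z_v1_f1")
    assert _terms_as_set(z1.definition.terms) == {
        (1.0, (), ()), (1.0, (("X2", -1.0),), ()), (1.0, (("X3", 1.0),), ())}
    z2 = gma_mm.aux_by_name("z_v2_X1")
    assert _terms_as_set(z2.definition.terms) == {
        (1.0, (), ()), (1.0, (("X1", 1.0),), ())}
    z3 = gma_mm.aux_by_name("z_v3_X2")
    assert _terms_as_set(z3.definition.terms) == {
        (1.0, (), ()), (1.0, (("X2", 2.0),), ())}


def test_mm_chain_aux_odes_match_hand_derivation(gma_mm):
    """zdot for K3^2 + X2^2 is 2 V2 X1 X2 z2^-1 - 2 V3 X2^3 z3^-1 (V2=8, V3=12),
    and zdot for the inhibition factor carries the K1*Ki X2^-2 chain-rule terms."""
    z3 = gma_mm.aux_by_name("z_v3_X2")
    assert _terms_as_set(z3.ode) == {
        (16.0, (("X1", 1.0), ("X2", 1.0), ("z_v2_X1", -1.0)), (("v2", 1.0),)),
        (-24.0, (("X2", 3.0), ("z_v3_X2", -1.0)), (("v3", 1.0),)),
    }
    z1 = gma_mm.aux_by_name("z_v1_f1")
    assert _terms_as_set(z1.ode) == {
        (12.0, (("z_v3_X2", -1.0),), (("v3", 1.0),)),
        (-8.0, (("X1", 1.0), ("X2", -2.0), ("z_v2_X1", -1.0)), (("v2", 1.0),)),
    }


def test_initial_aux_state_examples(gma_a, gma_mm):
    ones = {v: 1.0 for v in gma_a.dependent}
    z0 = initial_aux_state(gma_a, ones)
    assert z0["z_v4_X3"] == pytest.approx(2.0)   # 1 + 1
    assert z0["z_v3_X2"] == pytest.approx(1.25)  # 0.25 + 1
    assert z0["z_v1_X5"] == pytest.approx(2.0)   # K + X5 at X5 = 1
    z0mm = initial_aux_state(gma_mm, {"X1": 1.0, "X2": 2.0})
    assert z0mm["z_v1_f1"] == pytest.approx(1.0 * (1.0 + 1.0 / 2.0) + 2.0)
    assert z0mm["z_v2_X1"] == pytest.approx(2.0)
    assert z0mm["z_v3_X2"] == pytest.approx(5.0)


def test_initial_aux_state_rejects_bad_input(gma_a):
    with pytest.raises(DomainError):
        initial_aux_state(gma_a, {"X1": 1.0})  # missing variables
    with pytest.raises(DomainError):
        initial_aux_state(gma_a, {"X1": 0.0, "X2": 1.0, "X3": 1.0, "X4": 1.0})


def test_steady_state_system_counts_and_residual(gma_a):
    system = steady_state_system(gma_a)
    assert system.n_balance == 4
    assert system.n_link == 8
    assert len(system.unknowns) == 12
    ones = {v: 1.0 for v in gma_a.dependent}
    state = {**ones, **initial_aux_state(gma_a, ones)}
    assert np.max(np.abs(system.residual(state))) < 1e-10


def test_perturbing_one_z_breaks_exactly_one_link(gma_a):
    system = steady_state_system(gma_a)
    ones = {v: 1.0 for v in gma_a.dependent}
    state = {**ones, **initial_aux_state(gma_a, ones)}
    state["z_v3_X2"] += 0.1
    res = system.residual(state)
    links = res[system.n_balance:]
    broken = np.flatnonzero(np.abs(links) > 1e-12)
    assert list(broken) == [list(gma_a.aux_names).index("z_v3_X2")]
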