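"""Rate-law evaluation, parameter translation, and SC <-> rational identity."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from scgma import (
    DomainError,
    Monomial,
    ParameterError,
    RationalRateLaw,
    SCRateLaw,
    Signomial,
    evaluate_rate,
    model_a,
    powerlaw_to_sc,
)


@pytest.mark.parametrize(
    "rid, state, expected",
    [
        ("v1", {"X5": 1.0}, 10.0),          # 20 * 1/(1+1)
        ("v3", {"X2": 1.0}, 6.0),           # 7.5 * 1/1.25
        ("v2", {"X1": 1.0, "X3": 1.0}, 10.0),  # inhibition factor 1/2 at X3=1
    ],
)
def test_reference_rates_at_unit_state(rid, state, expected):
    law = model_a().rate_laws[rid]
    assert evaluate_rate(law, state, k=1.0) == pytest.approx(expected, abs=1e-12)


def test_enzyme_multiplier_scales_rate_linearly():
    law = model_a().rate_laws["v3"]
    base = evaluate_rate(law, {"X2": 1.7})
    assert evaluate_rate(law, {"X2": 1.7}, k=2.5) == pytest.approx(2.5 * base, rel=1e-14)


def test_nonpositive_state_is_rejected_with_variable_name():
    law = model_a().rate_laws["v3"]
    with pytest.raises(DomainError, match="X2"):
        evaluate_rate(law, {"X2": 0.0})
    with pytest.raises(DomainError, match="X2"):
        evaluate_rate(law, {"X2": -1.0})
    with pytest.raises(DomainError, match="X2"):
        evaluate_rate(law, {})


def test_sc_law_parameter_validation():
    with pytest.raises(ParameterError):
        SCRateLaw.make(12.0, {"X3": 1.0}, {"X3": 0.0})  # K must be positive
    with pytest.raises(ParameterError):
        SCRateLaw.make(12.0, {"X3": 0.0}, {"X3": 1.0})  # order must be nonzero
    with pytest.raises(ParameterError):
        SCRateLaw.make(-1.0, {"X3": 1.0}, {"X3": 1.0})
    with pytest.raises(ParameterError):
        SCRateLaw.make(1.0, {"X3": 1.0}, {"X2": 1.0})  # mismatched keys


def test_rational_law_requires_positive_factor_coefficients():
    with pytest.raises(ParameterError):
        RationalRateLaw(
            numerator=Monomial.make(1.0, {"X1": 1.0}),
            denominator_factors=(Signomial.make(
                [Monomial.make(-0.5), Monomial.make(1.0, {"X1": 1.0})]),),
        )


@pytest.mark.parametrize(
    "f, p, n_expected, K_expected",
    [(1.0, 0.5, 2.0, 1.0), (0.5, 0.8, 2.5, 0.25)],
)
def test_powerlaw_translation_printed_examples(f, p, n_expected, K_expected):
    law = powerlaw_to_sc({"X2": f}, {"X2": p}, {"X2": 1.0}, operating_flux=6.0)
    assert law.orders_dict["X2"] == pytest.approx(n_expected)
    assert law.half_dict["X2"] == pytest.approx(K_expected)


def test_powerlaw_translation_recovers_model_a_v3():
    # translating (f=0.5, p=0.8, v0=6 at X2=1) must rebuild the printed term
    law = powerlaw_to_sc({"X2": 0.5}, {"X2": 0.8}, {"X2": 1.0}, operating_flux=6.0)
    assert law.limit_rate == pytest.approx(7.5)
    ref = model_a().rate_laws["v3"]
    for x in (0.2, 1.0, 3.7, 9.9):
        assert law.value({"X2": x}) == pytest.approx(ref.value({"X2": x}), rel=1e-12)


def test_powerlaw_translation_rejects_degenerate_saturation():
    for p in (0.0, 1.0, -0.2, 1.4):
        with pytest.raises(ParameterError):
            powerlaw_to_sc({"X1": 1.0}, {"X1": p}, {"X1": 1.0}, 1.0)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    f=st.floats(-3.0, 3.0).filter(lambda v: abs(v) > 1e-3),
    p=st.floats(0.05, 0.95),
    x0=st.floats(0.1, 10.0),
    v0=st.floats(0.1, 50.0),
)
def test_saturation_fraction_round_trip(f, p, x0, v0):
    """p = X0^n / (K + X0^n) must recover the input saturation fraction."""
    law = powerlaw_to_sc({"X": f}, {"X": p}, {"X": x0}, v0)
    recovered = law.saturation_fractions({"X": x0})["X"]
    assert recovered == pytest.approx(p, abs=1e-12)
    assert law.value({"X": x0}) == pytest.approx(v0, rel=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    x1=st.floats(0.05, 20.0),
    x3=st.floats(0.05, 20.0),
    k=st.floats(0.1, 10.0),
)
def test_sc_rational_conversion_is_lossless(x1, x3, k):
    """An SC law and its rational form agree pointwise."""
    law = model_a().rate_laws["v2"]
    rat = law.to_rational()
    state = {"X1": x1, "X3": x3}
    assert rat.value(state, k=k) == pytest.approx(law.value(state, k=k), rel=1e-12)
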