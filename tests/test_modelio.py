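"""YAML schema round trips and model-file validation."""

import yaml
import pytest

from scgma import builtin_models, model_a
from scgma.modelio import (
    gma_to_dict,
    load_network,
    network_from_dict,
    network_to_dict,
    save_network,
    validate_model_file,
)
from scgma.recast import recast_rational


@pytest.mark.parametrize("name", ["A", "B", "MM"])
def test_round_trip_is_lossless(tmp_path, name):
    net = builtin_models()[name]
    path = tmp_path / f"{name}.yaml"
    save_network(net, path)
    assert load_network(path) == net


def test_round_trip_through_dict_preserves_rates():
    net = model_a()
    clone = network_from_dict(network_to_dict(net))
    state = {"X1": 0.7, "X2": 1.9, "X3": 0.4, "X4": 2.2}
    assert clone.fluxes(state) == pytest.approx(net.fluxes(state), rel=1e-15)


def test_gma_export_records_auxiliary_block():
    doc = gma_to_dict(recast_rational(model_a()))
    assert {a["name"] for a in doc["auxiliary"]} == {
        "z_v1_X5", "z_v2_X1", "z_v2_X3", "z_v3_X2",
        "z_v4_X3", "z_v5_X1", "z_v5_X2", "z_v6_X4"}
    for r in doc["reactions"]:
        assert r["rate"]["type"] == "gma"
    z4 = next(a for a in doc["auxiliary"] if a["name"] == "z_v4_X3")
    assert z4["definition"] == [{"coeff": 1.0}, {"coeff": 1.0, "powers": {"X3": 1.0}}]


def test_validation_passes_on_builtin_round_trip(tmp_path):
    path = tmp_path / "a.yaml"
    save_network(model_a(), path)
    assert validate_model_file(path) == []


def test_validation_flags_zero_half_constant(tmp_path):
    doc = network_to_dict(model_a())
    for r in doc["reactions"]:
        if r["id"] == "v3":
            r["rate"]["K"]["X2"] = 0.0
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(doc))
    diags = validate_model_file(path)
    assert any(d.level == "error" and "v3" in d.context for d in diags)


def test_validation_flags_undeclared_symbols(tmp_path):
    doc = network_to_dict(model_a())
    doc["reactions"][0]["stoichiometry"] = {"X99": 1.0}
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump(doc))
    diags = validate_model_file(path)
    assert any("X99" in d.message for d in diags)


def test_validation_reports_parse_failures(tmp_path):
    path = tmp_path / "broken.yaml"
    path.write_text("variables: [::")
    diags = validate_model_file(path)
    assert diags and diags[0].level == "error"


def test_validation_missing_file_raises(tmp_path):
    with pytest.raises(IOError):
        validate_model_file(tmp_path / "nope.yaml")


def test_state_report_lists_fluxes_and_derivatives(tmp_path):
    from scgma.modelio import state_report
    path = tmp_path / "state.tsv"
    frame = state_report(model_a(), [1.0, 1.0, 1.0, 1.0], path=path)
    fluxes = frame[frame.quantity == "flux"].set_index("id")["value"]
    assert fluxes["v1"] == pytest.approx(10.0)
    derivs = frame[frame.quantity == "derivative"]["value"]
    assert (derivs.abs() < 1e-12).all()
    assert path.read_text().startswith("quantity\tid\tvalue")


def test_scenario_round_trip(tmp_path):
    from scgma import scenario
    from scgma.modelio import load_scenario, save_scenario
    for name, obj in [("O1", "X3"), ("O3", "v4"), ("O4", "v4"), ("O5", "v6")]:
        scen = scenario(name, obj)
        path = tmp_path / f"{name}.yaml"
        save_scenario(scen, path)
        assert load_scenario(path) == scen
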