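"""Structured-text (YAML) schemas for models and scenarios, plus validation.

Model schema::

    name: model-A
    variables:
      - {name: X1, role: dependent}
      - {name: X5, role: independent, value: 1.0}
    reactions:
      - id: v1
        stoichiometry: {X1: 1.0}
        rate:
          type: sc                    # sc | powerlaw | rational
          limit_rate: 20.0
          orders: {X5: 1.0}
          K: {X5: 1.0}
    operating_point: {X1: 1.0, ...}   # optional

Rational rates carry ``numerator: {coeff, powers}`` and
``factors: [{parent?, terms: [{coeff, powers}]}]``.  Recast (GMA) models are
written with ``rate: {type: gma, coeff, powers}`` plus an ``auxiliary`` block
recording each z variable's defining expression so the link constraints can
be reconstructed.  Round trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import (
    Monomial,
    ParameterError,
    PowerLawRate,
    RationalRateLaw,
    RateLaw,
    ReactionNetwork,
    SCRateLaw,
    Signomial,
)
from .recast import GMAModel

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "gma_to_dict",
    "save_gma",
    "state_report",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "save_scenario",
    "Diagnostic",
    "validate_model_file",
]


def _mono_to_dict(m: Monomial) -> dict:
    d: dict = {"coeff": m.coeff}
    if m.powers:
        d["powers"] = {v: e for v, e in m.powers}
    if m.k_powers:
        d["k_powers"] = {r: e for r, e in m.k_powers}
    return d


def _mono_from_dict(d: dict) -> Monomial:
    return Monomial.make(d["coeff"], d.get("powers") or {}, d.get("k_powers") or {})


def _rate_to_dict(law: RateLaw) -> dict:
    if isinstance(law, SCRateLaw):
        return {"type": "sc", "limit_rate": law.limit_rate,
                "orders": law.orders_dict, "K": law.half_dict}
    if isinstance(law, PowerLawRate):
        return {"type": "powerlaw", "rate_constant": law.rate_constant,
                "orders": law.orders_dict}
    if isinstance(law, RationalRateLaw):
        factors = []
        parents = law.factor_parents or (None,) * len(law.denominator_factors)
        for f, parent in zip(law.denominator_factors, parents):
            entry: dict = {"terms": [_mono_to_dict(t) for t in f.terms]}
            if parent is not None:
                entry["parent"] = parent
            factors.append(entry)
        return {"type": "rational", "numerator": _mono_to_dict(law.numerator),
                "factors": factors}
    raise ParameterError(f"unsupported rate law type {type(law).__name__}")


def _rate_from_dict(d: dict) -> RateLaw:
    kind = d.get("type")
    if kind == "sc":
        return SCRateLaw.make(d["limit_rate"], d["orders"], d["K"])
    if kind == "powerlaw":
        return PowerLawRate.make(d["rate_constant"], d["orders"])
    if kind == "rational":
        factors = tuple(Signomial.make([_mono_from_dict(t) for t in f["terms"]])
                        for f in d["factors"])
        parents = tuple(f.get("parent") for f in d["factors"])
        return RationalRateLaw(numerator=_mono_from_dict(d["numerator"]),
                               denominator_factors=factors, factor_parents=parents)
    raise ParameterError(f"unknown rate type {kind!r}")


def network_to_dict(net: ReactionNetwork,
                    operating_point: dict[str, float] | None = None) -> dict:
    doc: dict = {
        "name": net.name,
        "variables": ([{"name": v, "role": "dependent"} for v in net.dependent]
                      + [{"name": v, "role": "independent", "value": x}
                         for v, x in net.independent]),
        "reactions": [{"id": rid,
                       "stoichiometry": net.stoich_dict.get(rid, {}),
                       "rate": _rate_to_dict(law)}
                      for rid, law in net.reactions],
    }
    if operating_point:
        doc["operating_point"] = dict(operating_point)
    return doc


def network_from_dict(doc: dict) -> ReactionNetwork:
    dependent = [v["name"] for v in doc["variables"] if v["role"] == "dependent"]
    independent = {v["name"]: float(v["value"])
                   for v in doc["variables"] if v["role"] == "independent"}
    reactions = {r["id"]: _rate_from_dict(r["rate"]) for r in doc["reactions"]}
    stoich = {r["id"]: {v: float(mu) for v, mu in (r.get("stoichiometry") or {}).items()}
              for r in doc["reactions"]}
    return ReactionNetwork.make(doc.get("name", "model"), dependent, independent,
                                reactions, stoich)


def save_network(net: ReactionNetwork, path: str | Path,
                 operating_point: dict[str, float] | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(network_to_dict(net, operating_point),
                                         sort_keys=False))


def load_network(path: str | Path) -> ReactionNetwork:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: not a mapping at top level")
    return network_from_dict(doc)


def gma_to_dict(gma: GMAModel) -> dict:
    """Recast model with rate type "gma" and an auxiliary-variable block."""
    return {
        "name": gma.name,
        "variables": ([{"name": v, "role": "dependent"} for v in gma.dependent]
                      + [{"name": v, "role": "independent", "value": x}
                         for v, x in gma.independent]),
        "reactions": [{"id": rid,
                       "stoichiometry": gma.source.stoich_dict.get(rid, {}),
                       "rate": {"type": "gma", **_mono_to_dict(mono)}}
                      for rid, mono in gma.rates],
        "auxiliary": [{"name": a.name, "reaction": a.reaction,
                       **({"parent": a.parent} if a.parent is not None else {}),
                       "definition": [_mono_to_dict(t) for t in a.definition.terms],
                       "ode": [_mono_to_dict(t) for t in a.ode]}
                      for a in gma.aux],
    }


def save_gma(gma: GMAModel, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(gma_to_dict(gma), sort_keys=False))


def state_report(net: ReactionNetwork, state, k=None, path: str | Path | None = None):
    """Fluxes and node derivatives at a given state as a DataFrame (or TSV).

    One row per reaction (flux) and one per variable (time derivative).
    """
    import pandas as pd

    from .model import node_derivatives

    if not isinstance(state, dict):
        state = {v: float(x) for v, x in zip(net.dependent, state)}
    fluxes = net.fluxes(state, k)
    derivs = node_derivatives(net, state, k)
    rows = [{"quantity": "flux", "id": rid, "value": val}
            for rid, val in fluxes.items()]
    rows += [{"quantity": "derivative", "id": var, "value": val}
             for var, val in derivs.items()]
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return frame


# -- scenario schema --------------------------------------------------------

def scenario_to_dict(scen) -> dict:
    doc: dict = {"name": scen.name, "objective": scen.objective,
                 "k_bounds": list(scen.k_bounds), "tol": scen.tol}
    if scen.x_bounds is not None:
        doc["x_bounds"] = (list(scen.x_bounds) if isinstance(scen.x_bounds, tuple)
                           else {v: list(b) for v, b in scen.x_bounds.items()})
    if scen.x_rel_band is not None:
        doc["x_rel_band"] = list(scen.x_rel_band)
    if scen.flux_bounds:
        doc["flux_bounds"] = {r: list(b) for r, b in scen.flux_bounds.items()}
    if scen.flux_rel_bands:
        doc["flux_rel_bands"] = {r: list(b) for r, b in scen.flux_rel_bands.items()}
    if scen.cardinality is not None:
        doc["cardinality"] = {"ME": scen.cardinality[0], "delta": scen.cardinality[1]}
    return doc


def scenario_from_dict(doc: dict):
    from .optimize import Scenario

    xb = doc.get("x_bounds")
    if isinstance(xb, list):
        xb = tuple(xb)
    elif isinstance(xb, dict):
        xb = {v: tuple(b) for v, b in xb.items()}
    card = doc.get("cardinality")
    return Scenario(
        name=doc.get("name", ""),
        objective=doc["objective"],
        k_bounds=tuple(doc.get("k_bounds", (0.2, 5.0))),
        x_bounds=xb,
        x_rel_band=tuple(doc["x_rel_band"]) if "x_rel_band" in doc else None,
        flux_bounds={r: tuple(b) for r, b in (doc.get("flux_bounds") or {}).items()},
        flux_rel_bands={r: tuple(b) for r, b in (doc.get("flux_rel_bands") or {}).items()},
        cardinality=(int(card["ME"]), float(card["delta"])) if card else None,
        tol=float(doc.get("tol", 0.002)),
    )


def save_scenario(scen, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scen), sort_keys=False))


def load_scenario(path: str | Path):
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: not a mapping at top level")
    return scenario_from_dict(doc)


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    message: str
    context: str = ""


def validate_model_file(path: str | Path) -> list[Diagnostic]:
    """Schema and consistency checks with per-item context; empty when clean."""
    out: list[Diagnostic] = []
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        return [Diagnostic("error", f"YAML parse failure: {exc}")]
    if not isinstance(doc, dict):
        return [Diagnostic("error", "top level must be a mapping")]

    declared: set[str] = set()
    for i, v in enumerate(doc.get("variables") or []):
        ctx = f"variables[{i}]"
        if not isinstance(v, dict) or "name" not in v or "role" not in v:
            out.append(Diagnostic("error", "each variable needs name and role", ctx))
            continue
        declared.add(v["name"])
        if v["role"] == "independent":
            if "value" not in v:
                out.append(Diagnostic("error",
                                      f"independent variable {v['name']} needs a value", ctx))
            elif not (float(v["value"]) > 0):
                out.append(Diagnostic("error",
                                      f"independent variable {v['name']} must be positive", ctx))
        elif v["role"] != "dependent":
            out.append(Diagnostic("error", f"unknown role {v['role']!r}", ctx))
    reactions = doc.get("reactions") or []
    rids = set()
    for i, r in enumerate(reactions):
        ctx = f"reactions[{i}]"
        rid = r.get("id")
        if not rid:
            out.append(Diagnostic("error", "reaction without id", ctx))
            continue
        ctx = f"reaction {rid}"
        rids.add(rid)
        try:
            law = _rate_from_dict(r.get("rate") or {})
        except (ParameterError, KeyError, TypeError) as exc:
            out.append(Diagnostic("error", f"invalid rate law: {exc}", ctx))
            continue
        for var in law.variables():
            if var not in declared:
                out.append(Diagnostic("error",
                                      f"rate references undeclared variable {var!r}", ctx))
        for var in (r.get("stoichiometry") or {}):
            if var not in declared:
                out.append(Diagnostic("error",
                                      f"stoichiometry references undeclared variable {var!r}",
                                      ctx))
    if not out:
        try:
            network_from_dict(doc)
        except ParameterError as exc:
            out.append(Diagnostic("error", str(exc)))
    return out
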