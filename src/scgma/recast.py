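"""Exact recasting of SC / rational-rate networks into GMA canonical form.

For every denominator factor of every rate law an auxiliary variable ``z`` is
introduced equal to that factor (for an SC law the factors are
``K_rj + X_j^{n_rj}``, one per nonzero kinetic order).  Every reaction rate
then becomes a single power-law monomial in the extended variable set
``(X, z)``, and differentiating the defining expressions — with the metabolite
derivatives expanded into their own monomial sums — yields monomial ODEs for
the ``z`` as well.  The transformation is exact: trajectories and steady
states of the recast model map one-to-one onto the original model through the
link identities ``z = definition(X)``.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .model import (
    DomainError,
    Monomial,
    ParameterError,
    RationalRateLaw,
    PowerLawRate,
    ReactionNetwork,
    SCRateLaw,
    Signomial,
    combine_monomials,
)

__all__ = [
    "AuxiliaryVariable",
    "GMAModel",
    "SteadyStateSystem",
    "RecastTypeError",
    "recast_sc",
    "recast_rational",
    "initial_aux_state",
    "steady_state_system",
]


class RecastTypeError(TypeError):
    """A rate law of the wrong family was passed to a recasting routine."""


@dataclass(frozen=True)
class AuxiliaryVariable:
    """One auxiliary variable: ``z = definition(X)`` with a monomial ODE."""

    name: str
    reaction: str
    parent: str | None  # the saturating variable for SC-derived factors
    definition: Signomial
    ode: tuple[Monomial, ...]


@dataclass(frozen=True)
class GMAModel:
    """Recast canonical model: every rate and every ODE is monomial.

    Variables are the original dependent metabolites followed by the auxiliary
    ``z`` variables, ordered by (reaction, factor).  ``rates`` holds one
    monomial per reaction (enzyme multiplier carried in ``k_powers``);
    ``x_odes``/``z_odes`` are signed monomial sums.  Initial conditions for
    ``z`` follow from the defining expressions (see :func:`initial_aux_state`).
    """

    name: str
    source: ReactionNetwork
    dependent: tuple[str, ...]
    independent: tuple[tuple[str, float], ...]
    aux: tuple[AuxiliaryVariable, ...]
    rates: tuple[tuple[str, Monomial], ...]
    x_odes: tuple[tuple[str, tuple[Monomial, ...]], ...]

    @property
    def independent_dict(self) -> dict[str, float]:
        return dict(self.independent)

    @property
    def aux_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.aux)

    @property
    def variables(self) -> tuple[str, ...]:
        """Dynamic variables of the recast model: X then z."""
        return self.dependent + self.aux_names

    @property
    def rates_dict(self) -> dict[str, Monomial]:
        return dict(self.rates)

    @property
    def x_odes_dict(self) -> dict[str, tuple[Monomial, ...]]:
        return dict(self.x_odes)

    @property
    def z_odes_dict(self) -> dict[str, tuple[Monomial, ...]]:
        return {a.name: a.ode for a in self.aux}

    @property
    def odes(self) -> dict[str, tuple[Monomial, ...]]:
        out = self.x_odes_dict
        out.update(self.z_odes_dict)
        return out

    def aux_by_name(self, name: str) -> AuxiliaryVariable:
        for a in self.aux:
            if a.name == name:
                return a
        raise KeyError(name)


def _as_rational(rid: str, law) -> RationalRateLaw | PowerLawRate:
    if isinstance(law, RationalRateLaw):
        return law
    if isinstance(law, PowerLawRate):
        return law
    if isinstance(law, SCRateLaw):
        return law.to_rational()
    raise RecastTypeError(f"reaction {rid!r}: unsupported rate-law type {type(law).__name__}")


def _recast(network: ReactionNetwork, allow: tuple[type, ...], hint: str) -> GMAModel:
    for rid, law in network.reactions:
        if not isinstance(law, allow):
            raise RecastTypeError(
                f"reaction {rid!r} has a {type(law).__name__} rate law; {hint}")

    aux_meta: list[tuple[str, str, str | None, Signomial]] = []
    rate_monos: dict[str, Monomial] = {}
    for rid, law in network.reactions:
        rat = _as_rational(rid, law)
        if isinstance(rat, PowerLawRate):
            rate_monos[rid] = Monomial.make(rat.rate_constant, rat.orders_dict, {rid: 1.0})
            continue
        parents = rat.factor_parents or (None,) * len(rat.denominator_factors)
        powers = rat.numerator.powers_dict
        for i, (factor, parent) in enumerate(zip(rat.denominator_factors, parents)):
            zname = f"z_{rid}_{parent}" if parent is not None else f"z_{rid}_f{i + 1}"
            aux_meta.append((zname, rid, parent, factor))
            powers[zname] = powers.get(zname, 0.0) - 1.0
        rate_monos[rid] = Monomial.make(rat.numerator.coeff, powers, {rid: 1.0})

    # Metabolite ODEs: signed monomial sums over the extended variables.
    stoich = network.stoich_dict
    x_odes: dict[str, list[Monomial]] = {v: [] for v in network.dependent}
    for rid, _ in network.reactions:
        for var, mu in stoich.get(rid, {}).items():
            x_odes[var].append(rate_monos[rid].scaled(mu))
    x_odes_c = {v: combine_monomials(ms) for v, ms in x_odes.items()}

    # Auxiliary ODEs by the chain rule over each defining signomial, with the
    # metabolite derivatives substituted by their monomial sums so the result
    # is syntactically GMA.  Independent variables contribute nothing.
    dep_set = set(network.dependent)
    aux: list[AuxiliaryVariable] = []
    for zname, rid, parent, factor in aux_meta:
        terms: list[Monomial] = []
        for mono in factor.terms:
            for var, exp in mono.powers:
                if var not in dep_set:
                    continue
                # d/dt [c * X^e * rest] = c*e*X^{e-1}*rest * dX/dt
                base = {v: e for v, e in mono.powers}
                base[var] = base[var] - 1.0
                partial = Monomial.make(mono.coeff * exp,
                                        {v: e for v, e in base.items() if e != 0.0})
                for xterm in x_odes_c[var]:
                    terms.append(partial.times(xterm))
        aux.append(AuxiliaryVariable(zname, rid, parent, factor, combine_monomials(terms)))

    return GMAModel(
        name=f"{network.name}-rgma",
        source=network,
        dependent=tuple(network.dependent),
        independent=network.independent,
        aux=tuple(aux),
        rates=tuple(sorted(rate_monos.items(),
                           key=lambda kv: [rid for rid, _ in network.reactions].index(kv[0]))),
        x_odes=tuple((v, x_odes_c[v]) for v in network.dependent),
    )


def recast_sc(network: ReactionNetwork) -> GMAModel:
    """Recast a network whose rate laws are all SC (or pure power laws).

    One auxiliary variable ``z_{r}_{j} = K_rj + X_j^{n_rj}`` is created per
    nonzero kinetic order; pure power-law rates gain none.
    """
    return _recast(network, (SCRateLaw, PowerLawRate),
                   "use recast_rational for rational rate laws")


def recast_rational(network: ReactionNetwork) -> GMAModel:
    """Recast a network with rational (or SC, or power-law) rate laws.

    One auxiliary variable is created per denominator factor; SC laws are a
    special case (each factor ``K + X^n``) and produce the same model as
    :func:`recast_sc` up to naming.
    """
    return _recast(network, (SCRateLaw, PowerLawRate, RationalRateLaw),
                   "only SC, power-law and rational rate laws are recastable")


def initial_aux_state(gma: GMAModel, x0: Mapping[str, float]) -> dict[str, float]:
    """Auxiliary initial conditions: each ``z(0)`` equals its definition at ``x0``."""
    state = gma.independent_dict
    for var in gma.dependent:
        if var not in x0:
            raise DomainError(f"missing initial value for {var!r}")
        if not (float(x0[var]) > 0):
            raise DomainError(f"initial value for {var!r} must be strictly positive")
        state[var] = float(x0[var])
    return {a.name: a.definition.value(state) for a in gma.aux}


@dataclass(frozen=True)
class SteadyStateSystem:
    """Balance + link equations of the recast model.

    Balance: ``sum_r mu_ir k_r V_r prod X^n prod z^{-1} = 0`` per dependent
    metabolite.  Link: ``definition_rj(X) - z_rj = 0`` per auxiliary variable.
    A point satisfying all equations is a steady state of both the recast and
    the original model.
    """

    gma: GMAModel
    balances: tuple[tuple[str, tuple[Monomial, ...]], ...]
    links: tuple[tuple[str, Signomial], ...]

    @property
    def n_balance(self) -> int:
        return len(self.balances)

    @property
    def n_link(self) -> int:
        return len(self.links)

    @property
    def unknowns(self) -> tuple[str, ...]:
        return self.gma.variables

    def residual(self, state: Mapping[str, float],
                 k: Mapping[str, float] | None = None) -> np.ndarray:
        full = self.gma.independent_dict
        full.update({v: float(state[v]) for v in self.unknowns})
        out = []
        for _, terms in self.balances:
            out.append(sum(t.value(full, k) for t in terms))
        for zname, definition in self.links:
            out.append(definition.value(full) - full[zname])
        return np.asarray(out)


def steady_state_system(gma: GMAModel) -> SteadyStateSystem:
    """Extract the steady-state constraint system used for optimization."""
    return SteadyStateSystem(
        gma=gma,
        balances=gma.x_odes,
        links=tuple((a.name, a.definition) for a in gma.aux),
    )
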