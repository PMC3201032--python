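"""Kinetic network data model.

Networks of biochemical reactions with Saturable-and-Cooperative (SC),
rational, or power-law rate laws.  An SC rate law has the form

    v_r = k_r * V_r * prod_j X_j^{n_rj} / prod_j (K_rj + X_j^{n_rj})

where ``k_r`` is a dimensionless enzyme-activity multiplier (1 at the basal
state), ``V_r`` a limit rate, ``n_rj`` real kinetic orders (negative for
inhibition) and ``K_rj > 0`` half-saturation constants.  Node dynamics are
``dX_i/dt = sum_r mu_ir k_r v_r`` with signed stoichiometric coefficients
``mu_ir``.

All concentrations are strictly positive and in arbitrary units; the module
rejects nonpositive values rather than limiting-casing them, since the
power-law machinery downstream works in log space.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "DomainError",
    "ParameterError",
    "Monomial",
    "Signomial",
    "SCRateLaw",
    "PowerLawRate",
    "RationalRateLaw",
    "RateLaw",
    "BasalState",
    "ReactionNetwork",
    "evaluate_rate",
    "node_derivatives",
    "powerlaw_to_sc",
    "builtin_models",
    "model_a",
    "model_b",
    "mm_chain",
    "generate_random_sc",
]


class DomainError(ValueError):
    """A variable value is outside the admissible (strictly positive) domain."""


class ParameterError(ValueError):
    """A rate-law or generator parameter violates its constraints."""


def _as_sorted_tuple(mapping: Mapping[str, float]) -> tuple[tuple[str, float], ...]:
    return tuple(sorted((str(k), float(v)) for k, v in mapping.items()))


@dataclass(frozen=True)
class Monomial:
    """``coeff * prod_j var_j^e_j * prod_r k_r^d_r`` over strictly positive values.

    ``powers`` maps state variables (metabolites or auxiliary variables) to
    exponents; ``k_powers`` maps reaction ids to exponents of the enzyme
    multipliers carried along by the term.
    """

    coeff: float
    powers: tuple[tuple[str, float], ...] = ()
    k_powers: tuple[tuple[str, float], ...] = ()

    @staticmethod
    def make(coeff: float, powers: Mapping[str, float] | None = None,
             k_powers: Mapping[str, float] | None = None) -> "Monomial":
        return Monomial(float(coeff),
                        _as_sorted_tuple(powers or {}),
                        _as_sorted_tuple(k_powers or {}))

    @property
    def powers_dict(self) -> dict[str, float]:
        return dict(self.powers)

    @property
    def k_powers_dict(self) -> dict[str, float]:
        return dict(self.k_powers)

    def value(self, state: Mapping[str, float], k: Mapping[str, float] | None = None) -> float:
        out = self.coeff
        for var, exp in self.powers:
            x = _positive(var, state)
            out *= x ** exp
        for rid, exp in self.k_powers:
            kr = 1.0 if k is None else float(k.get(rid, 1.0))
            out *= kr ** exp
        return out

    def scaled(self, factor: float) -> "Monomial":
        return Monomial(self.coeff * factor, self.powers, self.k_powers)

    def times(self, other: "Monomial") -> "Monomial":
        powers: dict[str, float] = dict(self.powers)
        for var, exp in other.powers:
            powers[var] = powers.get(var, 0.0) + exp
        kp: dict[str, float] = dict(self.k_powers)
        for rid, exp in other.k_powers:
            kp[rid] = kp.get(rid, 0.0) + exp
        powers = {v: e for v, e in powers.items() if e != 0.0}
        kp = {r: e for r, e in kp.items() if e != 0.0}
        return Monomial.make(self.coeff * other.coeff, powers, kp)

    def variables(self) -> set[str]:
        return {var for var, _ in self.powers}


def combine_monomials(terms: list[Monomial]) -> tuple[Monomial, ...]:
    """Sum like terms (identical exponent signatures) and drop exact zeros."""
    acc: dict[tuple, Monomial] = {}
    for t in terms:
        key = (t.powers, t.k_powers)
        if key in acc:
            acc[key] = Monomial(acc[key].coeff + t.coeff, t.powers, t.k_powers)
        else:
            acc[key] = t
    out = [m for m in acc.values() if m.coeff != 0.0]
    out.sort(key=lambda m: (m.powers, m.k_powers))
    return tuple(out)


@dataclass(frozen=True)
class Signomial:
    """A finite sum of monomials with positive coefficients (plus constants)."""

    terms: tuple[Monomial, ...]

    @staticmethod
    def make(terms: list[Monomial]) -> "Signomial":
        return Signomial(combine_monomials(list(terms)))

    def value(self, state: Mapping[str, float], k: Mapping[str, float] | None = None) -> float:
        return sum(t.value(state, k) for t in self.terms)

    def variables(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            out |= t.variables()
        return out

    @property
    def constant(self) -> float:
        return sum(t.coeff for t in self.terms if not t.powers)


def _positive(var: str, state: Mapping[str, float]) -> float:
    try:
        x = float(state[var])
    except KeyError:
        raise DomainError(f"missing value for variable {var!r}") from None
    if not (x > 0.0) or not math.isfinite(x):
        raise DomainError(f"variable {var!r} must be strictly positive and finite, got {x!r}")
    return x


@dataclass(frozen=True)
class SCRateLaw:
    """Saturable-and-Cooperative rate law ``V * prod X^n / prod (K + X^n)``."""

    limit_rate: float
    kinetic_orders: tuple[tuple[str, float], ...]
    half_constants: tuple[tuple[str, float], ...]

    @staticmethod
    def make(limit_rate: float, kinetic_orders: Mapping[str, float],
             half_constants: Mapping[str, float]) -> "SCRateLaw":
        law = SCRateLaw(float(limit_rate), _as_sorted_tuple(kinetic_orders),
                        _as_sorted_tuple(half_constants))
        law._validate()
        return law

    def _validate(self) -> None:
        if not (self.limit_rate > 0):
            raise ParameterError(f"limit rate must be positive, got {self.limit_rate}")
        orders = dict(self.kinetic_orders)
        consts = dict(self.half_constants)
        if set(orders) != set(consts):
            raise ParameterError(
                f"kinetic orders {sorted(orders)} and half constants {sorted(consts)} "
                "must cover the same variables")
        for var, n in orders.items():
            if n == 0.0:
                raise ParameterError(f"kinetic order for {var!r} must be nonzero")
        for var, K in consts.items():
            if not (K > 0):
                raise ParameterError(f"half constant for {var!r} must be positive, got {K}")

    @property
    def orders_dict(self) -> dict[str, float]:
        return dict(self.kinetic_orders)

    @property
    def half_dict(self) -> dict[str, float]:
        return dict(self.half_constants)

    def variables(self) -> set[str]:
        return {v for v, _ in self.kinetic_orders}

    def value(self, state: Mapping[str, float], k: float = 1.0) -> float:
        consts = self.half_dict
        out = k * self.limit_rate
        for var, n in self.kinetic_orders:
            xn = _positive(var, state) ** n
            out *= xn / (consts[var] + xn)
        return out

    def saturation_fractions(self, operating_point: Mapping[str, float]) -> dict[str, float]:
        """p_rj = X0^n / (K + X0^n) at the operating point (each in (0,1))."""
        consts = self.half_dict
        out = {}
        for var, n in self.kinetic_orders:
            xn = _positive(var, operating_point) ** n
            out[var] = xn / (consts[var] + xn)
        return out

    def to_rational(self) -> "RationalRateLaw":
        """Lossless conversion: one denominator factor ``K + X^n`` per order."""
        factors = []
        parents = []
        consts = self.half_dict
        for var, n in self.kinetic_orders:
            factors.append(Signomial.make([
                Monomial.make(consts[var]),
                Monomial.make(1.0, {var: n}),
            ]))
            parents.append(var)
        return RationalRateLaw(
            numerator=Monomial.make(self.limit_rate, self.orders_dict),
            denominator_factors=tuple(factors),
            factor_parents=tuple(parents),
        )


@dataclass(frozen=True)
class PowerLawRate:
    """Power-law rate ``gamma * prod X^f`` (GMA-style single monomial)."""

    rate_constant: float
    kinetic_orders: tuple[tuple[str, float], ...]

    @staticmethod
    def make(rate_constant: float, kinetic_orders: Mapping[str, float]) -> "PowerLawRate":
        if not (rate_constant > 0):
            raise ParameterError(f"rate constant must be positive, got {rate_constant}")
        return PowerLawRate(float(rate_constant), _as_sorted_tuple(kinetic_orders))

    @property
    def orders_dict(self) -> dict[str, float]:
        return dict(self.kinetic_orders)

    def variables(self) -> set[str]:
        return {v for v, _ in self.kinetic_orders}

    def value(self, state: Mapping[str, float], k: float = 1.0) -> float:
        out = k * self.rate_constant
        for var, f in self.kinetic_orders:
            out *= _positive(var, state) ** f
        return out


@dataclass(frozen=True)
class RationalRateLaw:
    """Monomial numerator over a product of signomial denominator factors.

    Each factor is a sum of monomials with positive coefficients (possibly
    including a constant), strictly positive on the admissible box.
    ``factor_parents`` optionally records, per factor, the single variable the
    factor saturates in (set when converted from an SC law).
    """

    numerator: Monomial
    denominator_factors: tuple[Signomial, ...]
    factor_parents: tuple[str | None, ...] = ()

    def __post_init__(self):
        if not (self.numerator.coeff > 0):
            raise ParameterError("numerator coefficient must be positive")
        for i, f in enumerate(self.denominator_factors):
            if not f.terms:
                raise ParameterError(f"denominator factor {i} is empty")
            for t in f.terms:
                if not (t.coeff > 0):
                    raise ParameterError(
                        f"denominator factor {i} has a nonpositive coefficient {t.coeff}")
        if self.factor_parents and len(self.factor_parents) != len(self.denominator_factors):
            raise ParameterError("factor_parents length must match denominator_factors")

    def variables(self) -> set[str]:
        out = self.numerator.variables()
        for f in self.denominator_factors:
            out |= f.variables()
        return out

    def value(self, state: Mapping[str, float], k: float = 1.0) -> float:
        out = k * self.numerator.value(state)
        for f in self.denominator_factors:
            out /= f.value(state)
        return out


RateLaw = Union[SCRateLaw, PowerLawRate, RationalRateLaw]


def evaluate_rate(rate: RateLaw, state: Mapping[str, float], k: float = 1.0) -> float:
    """Evaluate one reaction rate at a strictly positive state, scaled by ``k``."""
    v = rate.value(state, k=k)
    if not math.isfinite(v):
        raise DomainError(f"rate evaluated to a non-finite value {v!r}")
    return v


@dataclass(frozen=True)
class BasalState:
    """Steady state at unmodified enzyme activities (all k_r = 1)."""

    concentrations: dict[str, float]
    fluxes: dict[str, float]
    independent: dict[str, float]
    residual: float = 0.0


@dataclass(frozen=True)
class ReactionNetwork:
    """Stoichiometric network with per-reaction rate laws.

    ``stoichiometry`` maps reaction id -> {variable: mu} with signed
    coefficients; node ODEs are ``dX_i/dt = sum_r mu_ir k_r v_r``.
    ``independent`` variables enter rate laws at fixed values and have zero
    time derivative.
    """

    name: str
    dependent: tuple[str, ...]
    independent: tuple[tuple[str, float], ...]
    reactions: tuple[tuple[str, RateLaw], ...]
    stoichiometry: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]

    @staticmethod
    def make(name: str, dependent: list[str], independent: Mapping[str, float],
             reactions: Mapping[str, RateLaw],
             stoichiometry: Mapping[str, Mapping[str, float]]) -> "ReactionNetwork":
        net = ReactionNetwork(
            name=name,
            dependent=tuple(dependent),
            independent=tuple((str(v), float(x)) for v, x in independent.items()),
            reactions=tuple(reactions.items()),
            stoichiometry=tuple((rid, _as_sorted_tuple(mu))
                                for rid, mu in stoichiometry.items()),
        )
        net._validate()
        return net

    def _validate(self) -> None:
        declared = set(self.dependent) | {v for v, _ in self.independent}
        rids = [rid for rid, _ in self.reactions]
        if len(set(rids)) != len(rids):
            raise ParameterError("duplicate reaction ids")
        for var, x in self.independent:
            if not (x > 0):
                raise ParameterError(f"independent variable {var!r} must be positive, got {x}")
        stoich = dict(self.stoichiometry)
        for rid in stoich:
            if rid not in dict(self.reactions):
                raise ParameterError(f"stoichiometry references unknown reaction {rid!r}")
        for rid, law in self.reactions:
            for var in law.variables():
                if var not in declared:
                    raise ParameterError(
                        f"reaction {rid!r} references undeclared variable {var!r}")
            for var, _ in stoich.get(rid, ()):
                if var not in set(self.dependent):
                    raise ParameterError(
                        f"stoichiometry of {rid!r} references non-dependent variable {var!r}")

    # -- convenience views -------------------------------------------------
    @property
    def independent_dict(self) -> dict[str, float]:
        return dict(self.independent)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.reactions)

    @property
    def rate_laws(self) -> dict[str, RateLaw]:
        return dict(self.reactions)

    @property
    def stoich_dict(self) -> dict[str, dict[str, float]]:
        return {rid: dict(mu) for rid, mu in self.stoichiometry}

    def full_state(self, state: Mapping[str, float]) -> dict[str, float]:
        full = dict(self.independent)
        full.update({v: float(state[v]) for v in self.dependent})
        return full

    def fluxes(self, state: Mapping[str, float],
               k: Mapping[str, float] | None = None) -> dict[str, float]:
        full = self.full_state(state)
        out = {}
        for rid, law in self.reactions:
            kr = 1.0 if k is None else float(k.get(rid, 1.0))
            out[rid] = evaluate_rate(law, full, k=kr)
        return out

    def with_independent(self, values: Mapping[str, float]) -> "ReactionNetwork":
        """Copy of the network with some fixed independent values overridden."""
        indep = self.independent_dict
        for var, x in values.items():
            if var not in indep:
                raise ParameterError(f"{var!r} is not an independent variable")
            indep[var] = float(x)
        return ReactionNetwork.make(self.name, list(self.dependent), indep,
                                    self.rate_laws, self.stoich_dict)


def node_derivatives(network: ReactionNetwork, state: Mapping[str, float],
                     k: Mapping[str, float] | None = None) -> dict[str, float]:
    """Time derivatives ``dX_i/dt = sum_r mu_ir k_r v_r`` (zero for independents)."""
    v = network.fluxes(state, k)
    out = {var: 0.0 for var in network.dependent}
    for rid, mu in network.stoichiometry:
        for var, coef in mu:
            out[var] += coef * v[rid]
    for var, _ in network.independent:
        out[var] = 0.0
    return out


def powerlaw_to_sc(kinetic_orders: Mapping[str, float],
                   saturation_fractions: Mapping[str, float],
                   operating_point: Mapping[str, float],
                   operating_flux: float) -> SCRateLaw:
    """Translate power-law orders + saturation fractions into an SC law.

    ``n_j = f_j / (1 - p_j)``, ``K_j = ((1 - p_j)/p_j) * X_{j0}^{n_j}``, with the
    limit rate fixed so the SC rate reproduces the operating flux at the
    operating point.
    """
    if not (operating_flux > 0):
        raise ParameterError(f"operating flux must be positive, got {operating_flux}")
    if set(kinetic_orders) != set(saturation_fractions):
        raise ParameterError("orders and saturation fractions must cover the same variables")
    orders: dict[str, float] = {}
    consts: dict[str, float] = {}
    for var, f in kinetic_orders.items():
        p = float(saturation_fractions[var])
        if not (0.0 < p < 1.0):
            raise ParameterError(f"saturation fraction for {var!r} must lie in (0,1), got {p}")
        x0 = _positive(var, operating_point)
        n = f / (1.0 - p)
        orders[var] = n
        consts[var] = (1.0 - p) / p * x0 ** n
    shape = 1.0
    for var, n in orders.items():
        xn = float(operating_point[var]) ** n
        shape *= xn / (consts[var] + xn)
    return SCRateLaw.make(operating_flux / shape, orders, consts)


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------

def model_a(x5: float = 1.0) -> ReactionNetwork:
    """Branched four-metabolite reference network (feedback on v2, feedforward v5).

    The source metabolite X5 is fixed; its value is not part of the printed
    parameter set and defaults to the value that makes (1,1,1,1) the basal
    steady state at k=1, with fluxes (10, 10, 6, 6, 4, 4).
    """
    sc = SCRateLaw.make
    reactions = {
        "v1": sc(20.0, {"X5": 1.0}, {"X5": 1.0}),
        "v2": sc(40.0, {"X1": 1.0, "X3": -2.0}, {"X1": 1.0, "X3": 1.0}),
        "v3": sc(7.5, {"X2": 2.5}, {"X2": 0.25}),
        "v4": sc(12.0, {"X3": 1.0}, {"X3": 1.0}),
        "v5": sc(16.0, {"X1": 1.0, "X2": 1.0}, {"X1": 1.0, "X2": 1.0}),
        "v6": sc(8.0, {"X4": 1.0}, {"X4": 1.0}),
    }
    stoich = {
        "v1": {"X1": 1.0},
        "v2": {"X1": -1.0, "X2": 1.0},
        "v3": {"X2": -1.0, "X3": 1.0},
        "v4": {"X3": -1.0},
        "v5": {"X2": -1.0, "X4": 1.0},
        "v6": {"X4": -1.0},
    }
    return ReactionNetwork.make("model-A", ["X1", "X2", "X3", "X4"], {"X5": x5},
                                reactions, stoich)


def model_b(x5: float = 2.0) -> ReactionNetwork:
    """Same topology as model A with steeper, harder-to-optimize kinetics."""
    sc = SCRateLaw.make
    reactions = {
        "v1": sc(11.11, {"X5": 2.86}, {"X5": 0.81}),
        "v2": sc(12.35, {"X1": 1.54, "X3": -6.81}, {"X1": 0.61, "X3": 0.11}),
        "v3": sc(4.44, {"X2": 4.14}, {"X2": 0.11}),
        "v4": sc(4.44, {"X3": 4.14}, {"X3": 0.11}),
        "v5": sc(7.41, {"X1": 0.51, "X2": 26.51}, {"X1": 0.19, "X2": 0.11}),
        "v6": sc(6.67, {"X4": 1.57}, {"X4": 1.40}),
    }
    stoich = {
        "v1": {"X1": 1.0},
        "v2": {"X1": -1.0, "X2": 1.0},
        "v3": {"X2": -1.0, "X3": 1.0},
        "v4": {"X3": -1.0},
        "v5": {"X2": -1.0, "X4": 1.0},
        "v6": {"X4": -1.0},
    }
    return ReactionNetwork.make("model-B", ["X1", "X2", "X3", "X4"], {"X5": x5},
                                reactions, stoich)


def mm_chain(V1: float = 10.0, K1: float = 1.0, Ki: float = 1.0,
             V2: float = 8.0, K2: float = 1.0,
             V3: float = 12.0, K3: float = 1.0,
             x3: float = 2.0) -> ReactionNetwork:
    """Linear two-metabolite Michaelis-Menten chain with competitive inhibition.

    v1 = V1*X3 / (K1*(1 + Ki/X2) + X3)   (X2 competitively inhibits the entry step)
    v2 = V2*X1 / (K2 + X1)
    v3 = V3*X2^2 / (K3^2 + X2^2)

    X3 is the fixed source.  The rate-law structure is the interesting part
    (the first denominator factor is a genuine signomial,
    K1 + K1*Ki*X2^{-1} + X3); the numeric defaults are package choices that
    place a stable positive steady state near X=(1.4, 0.8).
    """
    v1 = RationalRateLaw(
        numerator=Monomial.make(V1, {"X3": 1.0}),
        denominator_factors=(Signomial.make([
            Monomial.make(K1),
            Monomial.make(K1 * Ki, {"X2": -1.0}),
            Monomial.make(1.0, {"X3": 1.0}),
        ]),),
        factor_parents=(None,),
    )
    v2 = RationalRateLaw(
        numerator=Monomial.make(V2, {"X1": 1.0}),
        denominator_factors=(Signomial.make([
            Monomial.make(K2), Monomial.make(1.0, {"X1": 1.0})]),),
        factor_parents=("X1",),
    )
    v3 = RationalRateLaw(
        numerator=Monomial.make(V3, {"X2": 2.0}),
        denominator_factors=(Signomial.make([
            Monomial.make(K3 ** 2), Monomial.make(1.0, {"X2": 2.0})]),),
        factor_parents=("X2",),
    )
    reactions = {"v1": v1, "v2": v2, "v3": v3}
    stoich = {
        "v1": {"X1": 1.0},
        "v2": {"X1": -1.0, "X2": 1.0},
        "v3": {"X2": -1.0},
    }
    return ReactionNetwork.make("mm-chain", ["X1", "X2"], {"X3": x3}, reactions, stoich)


def builtin_models() -> dict[str, ReactionNetwork]:
    """The three reference fixtures: SC models A and B, and the MM chain."""
    return {"A": model_a(), "B": model_b(), "MM": mm_chain()}


# ---------------------------------------------------------------------------
# Random SC network generator (property-test fixtures)
# ---------------------------------------------------------------------------

def generate_random_sc(seed: int, n_vars: int = 4, n_reactions: int = 6,
                       order_range: tuple[float, float] = (0.5, 3.0),
                       K_range: tuple[float, float] = (0.1, 2.0)) -> ReactionNetwork:
    """Random connected branched SC network with a built-in steady state.

    The generator lays down a source -> X1 -> ... -> Xn -> sink backbone plus
    random extra conversion/exit reactions, assigns consistent positive fluxes
    by forward balancing, forces at least one inhibitory (negative-order)
    modifier, and fixes each limit rate so the all-ones state is an exact
    steady state.  Deterministic per seed.
    """
    if n_vars < 1:
        raise ParameterError("need at least one dependent variable")
    if n_reactions < n_vars + 1:
        raise ParameterError(
            f"need at least {n_vars + 1} reactions for a chain over {n_vars} variables")
    lo_n, hi_n = order_range
    lo_K, hi_K = K_range
    if not (0 < lo_n <= hi_n) or not (0 < lo_K <= hi_K):
        raise ParameterError("order_range and K_range must be positive and ordered")
    rng = np.random.default_rng(seed)

    deps = [f"X{i + 1}" for i in range(n_vars)]
    source = "X0"
    n_extra = n_reactions - (n_vars + 1)

    # Topology: backbone chain + extra random conversions/exits.
    # substrate, product (None = sink), flux.
    edges: list[tuple[str, str | None]] = []
    edges.append((source, deps[0]))
    for i in range(n_vars - 1):
        edges.append((deps[i], deps[i + 1]))
    edges.append((deps[-1], None))
    extra_flux: list[float] = []
    for _ in range(n_extra):
        a = deps[int(rng.integers(n_vars))]
        if n_vars > 1 and rng.random() < 0.6:
            b = deps[int(rng.integers(n_vars))]
            while b == a:
                b = deps[int(rng.integers(n_vars))]
        else:
            b = None
        edges.append((a, b))
        extra_flux.append(float(rng.uniform(0.05, 0.25)))

    # Forward flux balancing: extras carry their sampled flux; the backbone
    # absorbs the remainder so every node balances at the all-ones state.
    source_flux = 2.0 + sum(extra_flux)
    flux: dict[int, float] = {0: source_flux}
    for idx in range(n_vars + 1, n_reactions):
        flux[idx] = extra_flux[idx - (n_vars + 1)]
    inflow = {v: 0.0 for v in deps}
    inflow[deps[0]] = source_flux
    for idx in range(n_vars + 1, n_reactions):
        a, b = edges[idx]
        inflow[a] -= flux[idx]
        if b is not None:
            inflow[b] += flux[idx]
    carry = 0.0
    for i in range(n_vars):
        carry = inflow[deps[i]] + carry
        flux[1 + i] = carry  # backbone reaction out of deps[i]
        if flux[1 + i] <= 0:
            raise ParameterError("internal error: nonpositive backbone flux")

    inhib_at = int(rng.integers(1, n_reactions))  # any non-source reaction
    reactions: dict[str, RateLaw] = {}
    stoich: dict[str, dict[str, float]] = {}
    for idx, (a, b) in enumerate(edges):
        rid = f"v{idx + 1}"
        orders = {a: float(rng.uniform(lo_n, hi_n))}
        consts = {a: float(rng.uniform(lo_K, hi_K))}
        candidates = [v for v in deps if v != a]
        add_inhibitor = (idx == inhib_at) or (candidates and rng.random() < 0.25)
        if add_inhibitor and candidates:
            m = candidates[int(rng.integers(len(candidates)))]
            orders[m] = -float(rng.uniform(lo_n, hi_n))
            consts[m] = float(rng.uniform(lo_K, hi_K))
        # Limit rate so that the rate at the all-ones state equals the flux:
        # every saturable factor is 1/(K+1) there.
        shape = 1.0
        for var in orders:
            shape *= 1.0 / (consts[var] + 1.0)
        reactions[rid] = SCRateLaw.make(flux[idx] / shape, orders, consts)
        mu: dict[str, float] = {}
        if a != source:
            mu[a] = -1.0
        if b is not None:
            mu[b] = 1.0
        stoich[rid] = mu
    return ReactionNetwork.make(f"random-sc-{seed}", deps, {source: 1.0},
                                reactions, stoich)
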