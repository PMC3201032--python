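"""Simulation and steady-state analysis of kinetic networks and recast models.

Provides a stiff-capable ODE front end (the recast auxiliary ODEs can be
stiff near saturation), a two-stage steady-state solver (damped root finding
in log space, with integrate-to-equilibrium as fallback), basal-state
derivation, and original-vs-recast trajectory equivalence reports.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import BasalState, DomainError, ReactionNetwork, SCRateLaw, PowerLawRate
from .recast import GMAModel, initial_aux_state

__all__ = [
    "Trajectory",
    "SteadyStateResult",
    "IntegrationError",
    "SteadyStateError",
    "NetworkEvaluator",
    "GMAEvaluator",
    "simulate",
    "find_steady_state",
    "basal_state",
    "equivalence_report",
    "EquivalenceReport",
]

_BLOWUP = 1e9


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


class SteadyStateError(RuntimeError):
    """No steady state found; carries the best residual norm achieved."""

    def __init__(self, message: str, best_residual: float):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class Trajectory:
    """Dense ODE solution on a monotone time grid (states strictly positive)."""

    t: np.ndarray
    values: np.ndarray  # (n_vars, n_times)
    columns: tuple[str, ...]
    rtol: float
    atol: float
    n_steps: int
    model_name: str = ""

    def __getitem__(self, var: str) -> np.ndarray:
        return self.values[self.columns.index(var)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=list(self.columns))
        df.insert(0, "time", self.t)
        return df

    def final_state(self) -> dict[str, float]:
        return {v: float(self.values[i, -1]) for i, v in enumerate(self.columns)}


@dataclass
class SteadyStateResult:
    """A steady state with its fluxes, residual norm and the method that found it."""

    state: dict[str, float]
    fluxes: dict[str, float]
    residual: float
    method: str  # "root" | "relaxation" | "relaxation+root"

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.state[v] for v in order])


# ---------------------------------------------------------------------------
# Compiled evaluators
# ---------------------------------------------------------------------------

class NetworkEvaluator:
    """Vectorized flux/derivative evaluation for a reaction network.

    SC and power-law rates are compiled to index arrays; rational laws fall
    back to their generic (dict-based) evaluation, which is fine for the
    small fixtures that use them.
    """

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.dep = list(network.dependent)
        self.rids = list(network.reaction_ids)
        self.n_dep = len(self.dep)
        self.n_rxn = len(self.rids)
        all_vars = self.dep + [v for v, _ in network.independent]
        self._vidx = {v: i for i, v in enumerate(all_vars)}
        self._fixed = np.array([x for _, x in network.independent])

    # stoichiometry matrix S (n_dep x n_rxn)
        S = np.zeros((self.n_dep, self.n_rxn))
        stoich = network.stoich_dict
        for j, rid in enumerate(self.rids):
            for var, mu in stoich.get(rid, {}).items():
                S[self.dep.index(var), j] = mu
        self.S = S

        self._compiled = []
        for rid, law in network.reactions:
            if isinstance(law, SCRateLaw):
                idx = np.array([self._vidx[v] for v, _ in law.kinetic_orders], dtype=int)
                n = np.array([e for _, e in law.kinetic_orders])
                consts = law.half_dict
                K = np.array([consts[v] for v, _ in law.kinetic_orders])
                self._compiled.append(("sc", law.limit_rate, idx, n, K))
            elif isinstance(law, PowerLawRate):
                idx = np.array([self._vidx[v] for v, _ in law.kinetic_orders], dtype=int)
                n = np.array([e for _, e in law.kinetic_orders])
                self._compiled.append(("pl", law.rate_constant, idx, n, None))
            else:
                self._compiled.append(("gen", law, None, None, None))

    def full_vector(self, x: np.ndarray) -> np.ndarray:
        return np.concatenate([x, self._fixed])

    def fluxes(self, x: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        full = self.full_vector(np.asarray(x, dtype=float))
        out = np.empty(self.n_rxn)
        for j, spec in enumerate(self._compiled):
            kind = spec[0]
            if kind == "sc":
                _, V, idx, n, K = spec
                with np.errstate(over="ignore", invalid="ignore"):
                    xn = full[idx] ** n
                    frac = np.where(np.isinf(xn), 1.0, xn / (K + xn))
                out[j] = V * np.prod(frac)
            elif kind == "pl":
                _, g, idx, n, _ = spec
                out[j] = g * np.prod(full[idx] ** n)
            else:
                law = spec[1]
                state = {v: full[i] for v, i in self._vidx.items()}
                out[j] = law.value(state)
        if k is not None:
            out = out * k
        return out

    def xdot(self, x: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        return self.S @ self.fluxes(x, k)

    def k_array(self, k: Mapping[str, float] | Sequence[float] | None) -> np.ndarray:
        if k is None:
            return np.ones(self.n_rxn)
        if isinstance(k, Mapping):
            return np.array([float(k.get(rid, 1.0)) for rid in self.rids])
        arr = np.asarray(k, dtype=float)
        if arr.shape != (self.n_rxn,):
            raise ValueError(f"expected {self.n_rxn} enzyme multipliers, got shape {arr.shape}")
        return arr


class GMAEvaluator:
    """Vectorized ODE right-hand side for a recast GMA model.

    Independent variables are folded into the term coefficients at build
    time, so each ODE is evaluated as a signed sum of
    ``exp(log c + E @ log x + Ek @ log k)`` terms.
    """

    def __init__(self, gma: GMAModel):
        self.gma = gma
        self.vars = list(gma.variables)
        self.rids = [rid for rid, _ in gma.rates]
        vidx = {v: i for i, v in enumerate(self.vars)}
        ridx = {r: i for i, r in enumerate(self.rids)}
        indep = gma.independent_dict
        rows = []
        coeffs = []
        E_rows = []
        Ek_rows = []
        for var, terms in gma.odes.items():
            vi = vidx[var]
            for m in terms:
                c = m.coeff
                e = np.zeros(len(self.vars))
                ek = np.zeros(len(self.rids))
                for v, exp in m.powers:
                    if v in vidx:
                        e[vidx[v]] = exp
                    else:
                        c *= indep[v] ** exp
                for r, exp in m.k_powers:
                    ek[ridx[r]] = exp
                rows.append(vi)
                coeffs.append(c)
                E_rows.append(e)
                Ek_rows.append(ek)
        self._owner = np.array(rows, dtype=int)
        self._sign = np.sign(coeffs)
        self._logc = np.log(np.abs(coeffs))
        self._E = np.array(E_rows)
        self._Ek = np.array(Ek_rows)
        self.n_vars = len(self.vars)

    def xdot(self, x: np.ndarray, k: np.ndarray | None = None) -> np.ndarray:
        logx = np.log(x)
        logk = np.zeros(len(self.rids)) if k is None else np.log(k)
        args = np.clip(self._logc + self._E @ logx + self._Ek @ logk, -745.0, 700.0)
        vals = self._sign * np.exp(args)
        out = np.zeros(self.n_vars)
        np.add.at(out, self._owner, vals)
        return out

    def k_array(self, k: Mapping[str, float] | Sequence[float] | None) -> np.ndarray:
        if k is None:
            return np.ones(len(self.rids))
        if isinstance(k, Mapping):
            return np.array([float(k.get(rid, 1.0)) for rid in self.rids])
        return np.asarray(k, dtype=float)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _normalize_x0(model, x0) -> tuple[list[str], np.ndarray]:
    if isinstance(model, GMAModel):
        columns = list(model.variables)
        if isinstance(x0, Mapping):
            x0 = dict(x0)
            missing_z = [a for a in model.aux_names if a not in x0]
            if missing_z:
                x0.update(initial_aux_state(model, x0))
            vec = np.array([float(x0[v]) for v in columns])
        else:
            arr = np.asarray(x0, dtype=float)
            if arr.size == len(model.dependent):
                x0m = {v: arr[i] for i, v in enumerate(model.dependent)}
                x0m.update(initial_aux_state(model, x0m))
                vec = np.array([x0m[v] for v in columns])
            elif arr.size == len(columns):
                vec = arr
            else:
                raise DomainError(
                    f"initial state must cover {len(model.dependent)} metabolites "
                    f"or all {len(columns)} recast variables")
    else:
        columns = list(model.dependent)
        if isinstance(x0, Mapping):
            vec = np.array([float(x0[v]) for v in columns])
        else:
            vec = np.asarray(x0, dtype=float)
            if vec.size != len(columns):
                raise DomainError(f"initial state must cover {len(columns)} metabolites")
    if np.any(vec <= 0) or not np.all(np.isfinite(vec)):
        raise DomainError("initial state must be strictly positive and finite")
    return columns, vec


def simulate(model: ReactionNetwork | GMAModel, x0, horizon: float,
             rel_tol: float = 1e-9, abs_tol: float = 1e-11,
             k: Mapping[str, float] | Sequence[float] | None = None,
             n_points: int = 201, method: str = "LSODA") -> Trajectory:
    """Integrate the model ODEs from ``x0`` over ``[0, horizon]``.

    ``x0`` may be a mapping or an array; for a recast model, auxiliary initial
    values are derived from the link definitions when not supplied.
    """
    if not (horizon > 0):
        raise ValueError("horizon must be positive")
    columns, y0 = _normalize_x0(model, x0)
    ev = GMAEvaluator(model) if isinstance(model, GMAModel) else NetworkEvaluator(model)
    karr = ev.k_array(k)
    t_eval = np.linspace(0.0, horizon, n_points)

    def rhs(t, y):
        return ev.xdot(np.maximum(y, 1e-300), karr)

    def blowup(t, y):
        return _BLOWUP - np.max(y)
    blowup.terminal = True

    sol = solve_ivp(rhs, (0.0, horizon), y0, method=method, t_eval=t_eval,
                    rtol=rel_tol, atol=abs_tol, events=blowup)
    if not sol.success or sol.t[-1] < horizon * (1 - 1e-12):
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(
            f"integration of {getattr(model, 'name', 'model')} stopped at t={last:.6g}: "
            f"{sol.message}", last)
    return Trajectory(t=sol.t, values=sol.y, columns=tuple(columns),
                      rtol=rel_tol, atol=abs_tol, n_steps=sol.t.size,
                      model_name=getattr(model, "name", ""))


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def _source_network(model) -> ReactionNetwork:
    return model.source if isinstance(model, GMAModel) else model


def find_steady_state(model: ReactionNetwork | GMAModel,
                      k: Mapping[str, float] | Sequence[float] | None = None,
                      guess: Mapping[str, float] | Sequence[float] | None = None,
                      tol: float = 1e-9,
                      evaluator: NetworkEvaluator | None = None) -> SteadyStateResult:
    """Find a strictly positive steady state.

    Strategy: root finding on the node equations in log space (unknowns
    ``ln X``, positivity for free), falling back to integrating towards
    equilibrium and polishing the endpoint by another root solve.  For a
    recast model the solve runs on the source metabolite space; auxiliary
    values then follow exactly from the link definitions.
    """
    network = _source_network(model)
    ev = evaluator if evaluator is not None else NetworkEvaluator(network)
    karr = ev.k_array(k)
    if guess is None:
        x0 = np.ones(ev.n_dep)
    elif isinstance(guess, Mapping):
        x0 = np.array([float(guess[v]) for v in ev.dep])
    else:
        x0 = np.asarray(guess, dtype=float)
    if np.any(x0 <= 0):
        raise DomainError("steady-state guess must be strictly positive")

    def fun(ly):
        return ev.xdot(np.exp(np.clip(ly, -300, 300)), karr)

    best_res = math.inf
    best_x = x0
    method = "root"
    sol = root(fun, np.log(x0), method="hybr", options={"xtol": 1e-13})
    x = np.exp(np.clip(sol.x, -300, 300))
    res = float(np.max(np.abs(ev.xdot(x, karr))))
    if res < best_res:
        best_res, best_x = res, x

    if best_res >= tol:
        # Relax towards equilibrium, escalating the horizon.
        method = "relaxation+root"
        y = x0.copy()
        try:
            for horizon in (50.0, 500.0, 5000.0):
                traj = simulate(network, y, horizon, rel_tol=1e-8, abs_tol=1e-10,
                                k=karr, n_points=41)
                y = np.array([traj.final_state()[v] for v in ev.dep])
                res = float(np.max(np.abs(ev.xdot(y, karr))))
                if res < 1e-10 * (1.0 + float(np.max(np.abs(y)))):
                    break
        except IntegrationError:
            pass
        if np.all(np.isfinite(y)) and np.all(y > 0):
            sol = root(fun, np.log(y), method="hybr", options={"xtol": 1e-13})
            x = np.exp(np.clip(sol.x, -300, 300))
            res = float(np.max(np.abs(ev.xdot(x, karr))))
            if res < best_res:
                best_res, best_x = res, x

    if not (best_res < tol):
        raise SteadyStateError(
            f"no steady state found (best residual {best_res:.3e} >= tol {tol:.1e})",
            best_res)

    state = {v: float(best_x[i]) for i, v in enumerate(ev.dep)}
    fluxes = {rid: float(f) for rid, f in zip(ev.rids, ev.fluxes(best_x, karr))}
    if isinstance(model, GMAModel):
        state.update(initial_aux_state(model, state))
    return SteadyStateResult(state=state, fluxes=fluxes, residual=best_res, method=method)


def basal_state(model: ReactionNetwork | GMAModel, tol: float = 1e-9) -> BasalState:
    """Steady state at unmodified enzyme activities (all k_r = 1)."""
    network = _source_network(model)
    res = find_steady_state(network, k=None, guess=None, tol=tol)
    return BasalState(concentrations={v: res.state[v] for v in network.dependent},
                      fluxes=res.fluxes,
                      independent=network.independent_dict,
                      residual=res.residual)


# ---------------------------------------------------------------------------
# Original vs recast equivalence
# ---------------------------------------------------------------------------

@dataclass
class EquivalenceReport:
    """Deviation between an original model and its recast over a trajectory."""

    max_abs: dict[str, float]
    max_rel: dict[str, float]
    link_drift: dict[str, float]
    horizon: float
    max_rel_overall: float = field(init=False)
    max_link_drift: float = field(init=False)

    def __post_init__(self):
        self.max_rel_overall = max(self.max_rel.values()) if self.max_rel else 0.0
        self.max_link_drift = max(self.link_drift.values()) if self.link_drift else 0.0


def equivalence_report(original: ReactionNetwork, recast: GMAModel, x0,
                       horizon: float, rel_tol: float = 1e-9, abs_tol: float = 1e-11,
                       k: Mapping[str, float] | None = None,
                       n_points: int = 201,
                       z0: Mapping[str, float] | None = None) -> EquivalenceReport:
    """Simulate both forms from matched initial conditions and compare.

    ``z0`` overrides the link-consistent auxiliary initial conditions (useful
    for demonstrating that an inconsistent start violates the link identity).
    """
    _, x0vec = _normalize_x0(original, x0)
    traj_o = simulate(original, x0vec, horizon, rel_tol, abs_tol, k=k, n_points=n_points)
    x0map = {v: float(x0vec[i]) for i, v in enumerate(original.dependent)}
    zinit = initial_aux_state(recast, x0map)
    if z0 is not None:
        zinit.update({z: float(v) for z, v in z0.items()})
    full0 = {**x0map, **zinit}
    traj_r = simulate(recast, full0, horizon, rel_tol, abs_tol, k=k, n_points=n_points)

    max_abs: dict[str, float] = {}
    max_rel: dict[str, float] = {}
    for var in original.dependent:
        a = traj_o[var]
        b = traj_r[var]
        d = np.abs(a - b)
        max_abs[var] = float(np.max(d))
        max_rel[var] = float(np.max(d / np.maximum(np.abs(a), 1e-12)))

    indep = recast.independent_dict
    link_drift: dict[str, float] = {}
    for a in recast.aux:
        z = traj_r[a.name]
        defs = np.empty_like(z)
        for i in range(traj_r.t.size):
            state = dict(indep)
            state.update({v: float(traj_r[v][i]) for v in recast.dependent})
            defs[i] = a.definition.value(state)
        link_drift[a.name] = float(np.max(np.abs(z - defs) / np.maximum(np.abs(defs), 1e-12)))
    return EquivalenceReport(max_abs=max_abs, max_rel=max_rel,
                             link_drift=link_drift, horizon=horizon)
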