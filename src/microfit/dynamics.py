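"""dFBA community simulator.

Couples per-species FBA to a single shared compound pool.  Each time step:

1. uptake bounds of every exchange reaction are limited by Monod kinetics,
   ``v_lb = -Vmax * C / (Ks + C)``, evaluated on the current pool;
2. each species' FBA problem is solved (and optionally made parsimonious so
   trajectories are reproducible when alternate optima exist);
3. biomass and pool concentrations advance by one forward-Euler step,
     dX_j/dt = (x_in_j - X_j) q/V + mu_j X_j
     dC_i/dt = (c_in_i - C_i) q/V + sum_j v_{j,i} X_j
4. the step is *augmented*: if a pool compound would be driven negative, the
   effective biomass of its consumers is scaled back proportionally so that
   consumption exactly matches what the step can supply; a grossly
   under-resolved drawdown of a stocked compound is instead retried at half
   the step size (down to dt / 2**10).

Biomass is confined to [0, Xmax] (a per-species theoretical cap) and pool
concentrations to [0, inf).  The effective exchange fluxes actually realized
after augmentation are recorded per step, so a discrete mass balance over a
closed (q = 0) trajectory closes to numerical precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .gem_core import FBASolution, IncrementalFBA, MetabolicModel

logger = logging.getLogger(__name__)

#: tolerance for flagging an exchange flux as sitting on its Monod bound
LIMITING_FLUX_TOL = 1e-6
#: maximum dt-halving recursion depth
MAX_SUBSTEP_DEPTH = 10
#: consecutive quiet steps required before the steady-state stop fires
STEADY_STATE_WINDOW = 5


class SubstepUnderflowError(RuntimeError):
    """A pool compound stayed negative even at the minimum sub-step size."""


class SimulationError(RuntimeError):
    """Generic unrecoverable simulation failure."""


@dataclass
class KineticParams:
    """Kinetic constants governing exchange with the shared pool.

    vmax : dict (species_id, exchange_reaction_id) -> Vmax, mmol/gDW/h
    ks : scalar half-saturation constant, mM (default 0.10)
    xmax : biomass cap, g/L — scalar or per-species dict (default 50)
    """

    vmax: dict[tuple[str, str], float]
    ks: float = 0.10
    xmax: float | dict[str, float] = 50.0

    def __post_init__(self) -> None:
        if self.ks <= 0:
            raise ValueError("ks must be positive")
        for key, v in self.vmax.items():
            if v < 0:
                raise ValueError(f"vmax for {key} is negative")
        if isinstance(self.xmax, (int, float)) and self.xmax <= 0:
            raise ValueError("xmax must be positive")

    def xmax_of(self, species_id: str) -> float:
        if isinstance(self.xmax, Mapping):
            return self.xmax[species_id]
        return float(self.xmax)

    def get_vmax(self, species_id: str, rxn_id: str) -> float:
        try:
            return self.vmax[(species_id, rxn_id)]
        except KeyError:
            raise KeyError(
                f"no Vmax for species {species_id!r}, reaction {rxn_id!r}"
            ) from None

    def copy(self) -> "KineticParams":
        xmax = dict(self.xmax) if isinstance(self.xmax, Mapping) else self.xmax
        return KineticParams(dict(self.vmax), self.ks, xmax)

    @classmethod
    def uniform(
        cls,
        models: Iterable[MetabolicModel],
        vmax0: float = 10.0,
        ks: float = 0.10,
        xmax: float = 50.0,
    ) -> "KineticParams":
        """Same Vmax on every uptake-capable exchange of every species."""
        vmax = {
            (m.species_id, rxn): float(vmax0)
            for m in models
            for rxn in m.uptake_exchanges()
        }
        return cls(vmax=vmax, ks=ks, xmax=xmax)


@dataclass
class ReactorConfig:
    """Reactor geometry, flow, medium and integration settings.

    The defaults describe a closed batch reactor (q = 0) of 1 L run for 24 h
    at dt = 0.1 h with early termination once the per-step relative change of
    the whole state drops below ``steady_state_accuracy``.
    """

    q: float = 0.0                      # flow rate, L/h
    V: float = 1.0                      # culture volume, L
    x_in: Mapping[str, float] = field(default_factory=dict)   # inflow biomass, g/L
    c_in: Mapping[str, float] = field(default_factory=dict)   # inflow conc., mM
    c0: Mapping[str, float] = field(default_factory=dict)     # initial medium, mM
    x0: float | Mapping[str, float] = 0.1                     # inoculum, g/L
    dt: float = 0.1                     # base step, h
    t_end: float = 24.0                 # horizon, h
    steady_state_accuracy: float = 1e-2  # <= 0 disables the early stop
    accuracy: float = 1e-9              # pool non-negativity tolerance
    bio_accuracy: float = 1e-9          # biomass non-negativity tolerance
    max_deviation: float = 25.0         # relative over-consumption triggering sub-steps
    biomass_reduction_factor: float = 8.0
    frozen_species: tuple[str, ...] = ()
    parsimonious: bool = True           # canonicalize alternate optima each solve

    def __post_init__(self) -> None:
        if self.q < 0 or self.V <= 0:
            raise ValueError("need q >= 0 and V > 0")
        if self.dt <= 0 or self.t_end < self.dt:
            raise ValueError("need dt > 0 and t_end >= dt")
        if any(v < 0 for v in self.c_in.values()):
            raise ValueError("inflow concentrations must be non-negative")

    def x0_of(self, species_id: str) -> float:
        if isinstance(self.x0, Mapping):
            return self.x0[species_id]
        return float(self.x0)


@dataclass
class CommunityState:
    """Community snapshot: biomass X (gDW/L) and pool concentrations C (mM)."""

    t: float
    species_ids: tuple[str, ...]
    X: np.ndarray
    compound_ids: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.X.shape != (len(self.species_ids),):
            raise ValueError("X length must match species_ids")
        if self.C.shape != (len(self.compound_ids),):
            raise ValueError("C length must match compound_ids")

    def copy(self) -> "CommunityState":
        return CommunityState(self.t, self.species_ids, self.X.copy(),
                              self.compound_ids, self.C.copy())


@dataclass
class StepRecord:
    """Effective rates realized over one recorded step.

    ``pool_fluxes[j, i]`` is the effective specific exchange rate of species j
    for pool compound i (mmol/gDW/h, negative = uptake), defined so that
    ``dt * pool_fluxes[j, i] * X_j(start)`` is exactly the amount species j
    transferred during the step; growth rates are averaged the same way.
    """

    growth_rates: np.ndarray            # (n_species,)
    pool_fluxes: np.ndarray             # (n_species, n_compounds)
    limiting: np.ndarray                # bool (n_species, n_compounds)


@dataclass
class Trajectory:
    """Recorded simulation: states plus realized rates per step."""

    states: list[CommunityState]
    records: list[StepRecord]
    species_ids: tuple[str, ...]
    compound_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        times = [s.t for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def final(self) -> CommunityState:
        return self.states[-1]

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def biomass(self) -> np.ndarray:
        """(n_states, n_species) biomass matrix."""
        return np.vstack([s.X for s in self.states])

    def concentrations(self) -> np.ndarray:
        """(n_states, n_compounds) pool concentration matrix."""
        return np.vstack([s.C for s in self.states])


# ---------------------------------------------------------------------------
# Monod-limited exchange bounds
# ---------------------------------------------------------------------------

def monod_rate(vmax: float, ks: float, s: float) -> float:
    """Monod saturation rate ``vmax * s / (ks + s)``.

    ``s`` must be non-negative; the caller clamps the pool first.
    """
    if vmax < 0:
        raise ValueError("vmax must be non-negative")
    if ks <= 0:
        raise ValueError("ks must be positive")
    if s < 0:
        raise ValueError(f"substrate concentration is negative ({s})")
    return vmax * s / (ks + s)


def exchange_bounds(
    model: MetabolicModel,
    params: KineticParams,
    C: Mapping[str, float],
) -> dict[str, tuple[float, float]]:
    """Monod uptake limits for every uptake-capable exchange reaction.

    The lower (uptake) bound becomes ``-monod_rate(Vmax, Ks, C[compound])``;
    the upper (secretion) bound is left untouched.  Exchanges whose default
    bounds forbid uptake (lb >= 0) keep their bounds: the Monod limit never
    widens a reaction the model declared irreversible.
    """
    overrides: dict[str, tuple[float, float]] = {}
    for rxn in model.uptake_exchanges():
        compound = model.exchange_map[rxn]
        if compound not in C:
            raise KeyError(
                f"pool compound {compound!r} (exchange {rxn!r} of "
                f"{model.species_id!r}) missing from pool"
            )
        i = model.reaction_index(rxn)
        limit = monod_rate(params.get_vmax(model.species_id, rxn),
                           params.ks, max(C[compound], 0.0))
        overrides[rxn] = (max(model.lb[i], -limit), model.ub[i])
    return overrides


# ---------------------------------------------------------------------------
# the augmented forward-Euler step
# ---------------------------------------------------------------------------

def _species_pool_fluxes(
    model: MetabolicModel,
    sol: FBASolution,
    compound_index: Mapping[str, int],
    n_compounds: int,
    overrides: Mapping[str, tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Map a flux vector onto pool compounds; flag Monod-limited uptakes."""
    row = np.zeros(n_compounds)
    limiting = np.zeros(n_compounds, dtype=bool)
    for rxn, compound in model.exchange_map.items():
        i = compound_index[compound]
        v = float(sol.fluxes[model.reaction_index(rxn)])
        row[i] += v
        if rxn in overrides:
            lo = overrides[rxn][0]
            if lo < 0 and abs(v - lo) <= LIMITING_FLUX_TOL:
                limiting[i] = True
    return row, limiting


def _solver_for(model: MetabolicModel, parsimonious: bool) -> IncrementalFBA:
    """Lazily attach a persistent LP to the model (built once, bounds
    updated in place on every step)."""
    cache = getattr(model, "_incremental_fba", None)
    if cache is None or cache.parsimonious != parsimonious:
        cache = IncrementalFBA(model, parsimonious=parsimonious)
        model._incremental_fba = cache  # type: ignore[attr-defined]
    return cache


def _solve_community(
    state: CommunityState,
    models: Sequence[MetabolicModel],
    params: KineticParams,
    reactor: ReactorConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-species FBA at the current pool: growth rates mu, pool flux
    matrix F (n_species x n_compounds) and Monod-limiting flags."""
    n_sp = len(models)
    n_cp = len(state.compound_ids)
    cindex = {c: i for i, c in enumerate(state.compound_ids)}
    pool = {c: max(float(state.C[i]), 0.0) for i, c in enumerate(state.compound_ids)}
    mu = np.zeros(n_sp)
    F = np.zeros((n_sp, n_cp))
    limiting = np.zeros((n_sp, n_cp), dtype=bool)
    for j, model in enumerate(models):
        if state.X[j] <= 0.0:
            continue
        overrides = exchange_bounds(model, params, pool)
        sol = _solver_for(model, reactor.parsimonious).solve(overrides)
        if not sol.optimal:
            continue
        mu[j] = max(sol.growth_rate, 0.0)
        F[j], limiting[j] = _species_pool_fluxes(
            model, sol, cindex, n_cp, overrides)
    return mu, F, limiting


def _euler_substep(
    state: CommunityState,
    models: Sequence[MetabolicModel],
    params: KineticParams,
    reactor: ReactorConfig,
    dt: float,
    depth: int,
    frozen: np.ndarray,
) -> tuple[CommunityState, np.ndarray, np.ndarray, np.ndarray]:
    """One (possibly recursively halved) Euler step.

    Returns the new state, the biomass growth increments (g/L), the realized
    pool transfer per (species, compound) in mM, and the limiting flags.
    """
    mu, F, limiting = _solve_community(state, models, params, reactor)
    X, C = state.X, state.C
    qV = reactor.q / reactor.V
    x_in = np.array([reactor.x_in.get(s, 0.0) for s in state.species_ids])
    c_in = np.array([reactor.c_in.get(c, 0.0) for c in state.compound_ids])
    c_flow = dt * (c_in - C) * qV

    # augmentation: ration each over-demanded compound's consumption.
    # Per compound, the step can supply the current stock plus this step's
    # inflow and production; if the consumers together demand more, every
    # consumption term is scaled by the common factor supply/demand (the
    # effective consuming biomass shrinks proportionally), which keeps the
    # pool exactly non-negative and — unlike a stepwise reduction factor —
    # leaves the realized transfers a continuous function of the kinetics.
    contrib = dt * F * X[:, None]
    production = np.where(contrib > 0, contrib, 0.0).sum(axis=0)
    demand = -np.where(contrib < 0, contrib, 0.0).sum(axis=0)
    supply = C + c_flow + production
    over = demand > supply + reactor.accuracy
    if over.any():
        # a grossly under-resolved drawdown of a *stocked* compound is
        # retried at half the step size (finer Monod re-evaluation); pure
        # flow-through deficits keep the same demand/supply ratio at any dt
        # and are rationed directly.
        ratio_over = demand / np.maximum(supply, reactor.accuracy)
        stocked = C > c_flow + production
        gross = over & stocked & (ratio_over > 1.0 + reactor.max_deviation)
        if gross.any() and depth < MAX_SUBSTEP_DEPTH:
            half = dt / 2.0
            s1, g1, tr1, lim1 = _euler_substep(
                state, models, params, reactor, half, depth + 1, frozen)
            s2, g2, tr2, lim2 = _euler_substep(
                s1, models, params, reactor, half, depth + 1, frozen)
            return s2, g1 + g2, tr1 + tr2, lim1 | lim2
        for i in np.flatnonzero(over):
            if supply[i] < -reactor.accuracy:
                raise SubstepUnderflowError(
                    f"pool compound {state.compound_ids[i]!r} cannot stay "
                    f"non-negative even with all consumption suppressed "
                    f"(t = {state.t:.3g} h, dt = {dt:.3g} h)"
                )
            scale = max(supply[i], 0.0) / demand[i]
            neg = contrib[:, i] < 0
            contrib[neg, i] *= scale
    C_new = np.maximum(C + c_flow + contrib.sum(axis=0), 0.0)

    # growth scales with the uptake each species actually realized, so the
    # exhaustion step stays a smooth function of the kinetic parameters
    requested = dt * np.where(F < 0, F, 0.0) * X[:, None]
    req_tot = -requested.sum(axis=1)
    got_tot = -np.where(contrib < 0, contrib, 0.0).sum(axis=1)
    ratio = np.where(req_tot > 0, got_tot / np.maximum(req_tot, 1e-300), 1.0)
    growth = dt * mu * X * np.minimum(ratio, 1.0)
    X_new = X + dt * (x_in - X) * qV + growth
    X_new[frozen] = X[frozen]
    xmax = np.array([params.xmax_of(s) for s in state.species_ids])
    X_new = np.clip(X_new, 0.0, xmax)
    new = CommunityState(state.t + dt, state.species_ids, X_new,
                         state.compound_ids, C_new)
    return new, growth, contrib, limiting


def step(
    state: CommunityState,
    models: Sequence[MetabolicModel],
    params: KineticParams,
    reactor: ReactorConfig,
) -> CommunityState:
    """Advance the community by one base step of ``reactor.dt`` hours."""
    new, _rec = step_with_record(state, models, params, reactor)
    return new


def step_with_record(
    state: CommunityState,
    models: Sequence[MetabolicModel],
    params: KineticParams,
    reactor: ReactorConfig,
) -> tuple[CommunityState, StepRecord]:
    """Advance one base step and report the effective rates realized."""
    if len(models) != len(state.species_ids):
        raise ValueError("one model per species required")
    frozen = np.array([s in reactor.frozen_species for s in state.species_ids])
    dt = reactor.dt
    new, growth, transfer, limiting = _euler_substep(
        state, models, params, reactor, dt, 0, frozen)
    denom = np.where(state.X > 0, state.X, 1.0) * dt
    rec = StepRecord(
        growth_rates=growth / denom,
        pool_fluxes=transfer / denom[:, None],
        limiting=limiting,
    )
    return new, rec


def initial_state(
    models: Sequence[MetabolicModel],
    reactor: ReactorConfig,
    compound_ids: Sequence[str] | None = None,
) -> CommunityState:
    """Build the t = 0 state from the reactor's inoculum and medium."""
    species_ids = tuple(m.species_id for m in models)
    if compound_ids is None:
        pool: dict[str, None] = {}
        for m in models:
            for c in m.exchange_map.values():
                pool.setdefault(c)
        for c in reactor.c0:
            pool.setdefault(c)
        for c in reactor.c_in:
            pool.setdefault(c)
        compound_ids = tuple(pool)
    X0 = np.array([reactor.x0_of(s) for s in species_ids])
    C0 = np.array([reactor.c0.get(c, 0.0) for c in compound_ids])
    return CommunityState(0.0, species_ids, X0, tuple(compound_ids), C0)


def simulate(
    models: Sequence[MetabolicModel],
    params: KineticParams,
    reactor: ReactorConfig,
    init: CommunityState | None = None,
) -> Trajectory:
    """Integrate the community from ``init`` (or the reactor's default
    initial state) until ``t_end`` or a steady state.

    The steady-state stop fires when the largest relative *rate* of change
    of any biomass or pool entry (fractional change per hour) stays below
    ``reactor.steady_state_accuracy`` for ``STEADY_STATE_WINDOW`` consecutive
    steps.  The rate form makes the criterion independent of the step size;
    the window keeps one-step lulls (e.g. a cross-feeding pipeline stalling
    for a single step while its producer is throttled) from terminating a
    community that is still growing.
    """
    if init is None:
        init = initial_state(models, reactor)
    if init.t >= reactor.t_end:
        raise ValueError("t_end must exceed the initial time")
    states = [init.copy()]
    records: list[StepRecord] = []
    state = init
    n_steps = int(round((reactor.t_end - init.t) / reactor.dt))
    quiet = 0
    for _ in range(max(n_steps, 1)):
        new, rec = step_with_record(state, models, params, reactor)
        states.append(new)
        records.append(rec)
        old = np.concatenate([state.X, state.C])
        cur = np.concatenate([new.X, new.C])
        rel = np.abs(cur - old) / np.maximum(np.abs(old), 1e-6) / reactor.dt
        state = new
        quiet = (quiet + 1
                 if reactor.steady_state_accuracy > 0
                 and float(rel.max()) < reactor.steady_state_accuracy
                 else 0)
        if quiet >= STEADY_STATE_WINDOW:
            logger.debug("steady state at t = %.3g h", state.t)
            break
    return Trajectory(states, records, init.species_ids, init.compound_ids)
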