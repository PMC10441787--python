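"""Synthetic communities: small feasible metabolic models, shared-pool
consortia with optional cross-feeding, and reference abundance profiles that
are attainable by forward simulation.

Every generator is a pure function of its seed.  The toy species model is a
minimal but fully valid stoichiometric network: one exchange per carbon
source, a conversion chain turning substrate into biomass precursor (with a
randomized yield), a biomass sink carrying the growth objective, and
optionally one secretion exchange releasing a byproduct into the pool —
the hook that lets a downstream species cross-feed.

Defaults (one config block; see docs/methods.md for rationale):
medium supplies 40 mM of the shared primary source, inocula are 0.1 g/L,
yields are uniform in [0.04, 0.10] gDW/mmol, hidden Vmax* for attainable
targets are log-uniform in [1, 20] mmol/gDW/h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dynamics import KineticParams, ReactorConfig, initial_state, simulate
from .fitting import AbundanceProfile, community_fractions
from .gem_core import MetabolicModel

# -- generator constants ----------------------------------------------------
# Yields bracket real heterotroph biomass yields on glucose (~0.09 gDW/mmol);
# together with Vmax* in [1, 20] mmol/gDW/h they keep specific growth rates
# below ~2 /h, which the forward-Euler scheme resolves at dt = 0.1 h.
YIELD_RANGE = (0.04, 0.10)      # gDW biomass per mmol substrate
VMAX_HIDDEN_RANGE = (1.0, 20.0)  # mmol/gDW/h, log-uniform
SECRETION_COEF = 0.3            # mmol byproduct per mmol substrate converted
PRIMARY_SOURCE = "glc"          # shared primary carbon source id
MEDIUM_CONC = 40.0              # mM primary source (~7 g/L glucose)
UPTAKE_CAP = 1000.0             # base uptake bound before Monod limits


@dataclass
class SyntheticCommunity:
    """A generated consortium ready to simulate."""

    models: list[MetabolicModel]
    pool_compounds: tuple[str, ...]
    medium: dict[str, float]     # mM


def generate_toy_model(
    species_id: str,
    carbon_sources: Sequence[str],
    seed: int,
    secretes: str | None = None,
) -> MetabolicModel:
    """A minimal feasible species model.

    One uptake exchange per carbon source feeding a conversion reaction
    ``source -> yield * biomass_precursor (+ secretion byproduct)``, a
    biomass sink with the growth objective, and optionally a secretion-only
    exchange for the byproduct.  Growth is guaranteed whenever any source is
    available (growth rate = yield * uptake rate at saturation).
    """
    if not carbon_sources:
        raise ValueError("need at least one carbon source")
    rng = np.random.default_rng(seed)
    metabolites = list(carbon_sources) + ["bio"]
    if secretes is not None:
        metabolites.append(secretes)
    mindex = {m: i for i, m in enumerate(metabolites)}
    reaction_ids: list[str] = []
    cols: list[np.ndarray] = []
    lb: list[float] = []
    ub: list[float] = []
    exchange_map: dict[str, str] = {}

    def add(rid: str, stoich: dict[str, float], lo: float, hi: float) -> None:
        col = np.zeros(len(metabolites))
        for m, s in stoich.items():
            col[mindex[m]] = s
        reaction_ids.append(rid)
        cols.append(col)
        lb.append(lo)
        ub.append(hi)

    for src in carbon_sources:
        rid = f"EX_{src}"
        add(rid, {src: -1.0}, -UPTAKE_CAP, 0.0)
        exchange_map[rid] = src
        y = float(rng.uniform(*YIELD_RANGE))
        stoich = {src: -1.0, "bio": y}
        if secretes is not None:
            stoich[secretes] = SECRETION_COEF
        add(f"CONV_{src}", stoich, 0.0, UPTAKE_CAP)
    add("BIOMASS", {"bio": -1.0}, 0.0, UPTAKE_CAP)
    if secretes is not None:
        rid = f"EX_{secretes}"
        add(rid, {secretes: -1.0}, 0.0, UPTAKE_CAP)
        exchange_map[rid] = secretes

    objective = np.zeros(len(reaction_ids))
    objective[reaction_ids.index("BIOMASS")] = 1.0
    return MetabolicModel(
        species_id=species_id,
        metabolite_ids=metabolites,
        reaction_ids=reaction_ids,
        S=np.column_stack(cols),
        lb=np.array(lb),
        ub=np.array(ub),
        objective=objective,
        biomass_reaction="BIOMASS",
        exchange_map=exchange_map,
    )


def generate_community(
    n_species: int,
    cross_feeding: bool = False,
    seed: int = 0,
) -> SyntheticCommunity:
    """A consortium competing for one shared primary source.

    With ``cross_feeding``, species k (k >= 2) can additionally consume the
    byproduct secreted by species k-1, so its extra niche only opens once the
    upstream species is active.  The medium supplies the primary source only.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_species)
    models: list[MetabolicModel] = []
    pool: dict[str, None] = {PRIMARY_SOURCE: None}
    for k in range(1, n_species + 1):
        sources = [PRIMARY_SOURCE]
        secretes = None
        if cross_feeding:
            if k >= 2:
                sources.append(f"byp{k - 1}")
            if k < n_species:
                secretes = f"byp{k}"
        model = generate_toy_model(
            f"sp{k}", sources, int(child_seeds[k - 1]), secretes=secretes)
        models.append(model)
        for c in model.exchange_map.values():
            pool.setdefault(c)
    medium = {PRIMARY_SOURCE: MEDIUM_CONC}
    return SyntheticCommunity(models, tuple(pool), medium)


def make_attainable_target(
    models: Sequence[MetabolicModel],
    reactor: ReactorConfig,
    seed: int = 0,
) -> tuple[AbundanceProfile, KineticParams]:
    """A reference profile known to be reachable by the simulator.

    Draws hidden Vmax* (log-uniform) for every uptake-capable exchange,
    simulates the community forward, and returns the final fractions as the
    reference plus the hidden parameters for recovery experiments.  The
    forward run uses the full horizon (no steady-state early stop) so the
    target is defined at the same end point the fitting loop evaluates.
    """
    from dataclasses import replace as _replace

    reactor = _replace(reactor, steady_state_accuracy=0.0)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(VMAX_HIDDEN_RANGE[0]), np.log(VMAX_HIDDEN_RANGE[1])
    # one hidden Vmax* per species, shared by all its uptake exchanges —
    # the same parameterization the fitting loop searches, so the returned
    # profile is attainable by construction
    vmax: dict[tuple[str, str], float] = {}
    for m in models:
        v = float(np.exp(rng.uniform(lo, hi)))
        for rxn in m.uptake_exchanges():
            vmax[(m.species_id, rxn)] = v
    hidden = KineticParams(vmax=vmax)
    init = initial_state(models, reactor)
    traj = simulate(models, hidden, reactor, init)
    final = traj.final.X
    if final.sum() <= 0 or np.all(final <= init.X * (1 + 1e-9)):
        raise RuntimeError(
            "forward run produced no growth; try a different seed")
    profile = AbundanceProfile(
        tuple(m.species_id for m in models), community_fractions(final))
    return profile, hidden
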