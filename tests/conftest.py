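"""Shared fixtures and the independent brute-force LP oracle.

The oracle enumerates candidate vertices of {S v = 0, lb <= v <= ub} by
fixing subsets of variables at their bounds and solving the remaining
square-ish system, entirely independent of the simplex path used by the
package.  Feasible for the <= 6-reaction networks used in tests.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from microfit import MetabolicModel, ReactorConfig
from microfit.synth import generate_community


def brute_force_lp_max(S, lb, ub, c, tol=1e-7):
    """Max of c.v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Returns None when no candidate vertex is feasible (infeasible LP).
    All bounds must be finite.
    """
    S = np.asarray(S, float)
    lb = np.asarray(lb, float)
    ub = np.asarray(ub, float)
    c = np.asarray(c, float)
    m, n = S.shape
    best = None
    for k in range(n + 1):
        for fixed in combinations(range(n), k):
            free = [j for j in range(n) if j not in fixed]
            choices = product(*[(lb[j], ub[j]) for j in fixed])
            for vals in choices:
                vals = np.array(vals)
                rhs = -S[:, fixed] @ vals if k else np.zeros(m)
                v = np.zeros(n)
                v[list(fixed)] = vals
                if free:
                    A = S[:, free]
                    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
                    if rank < len(free):
                        continue  # free part not pinned down: not a vertex
                    if np.max(np.abs(A @ sol - rhs)) > tol:
                        continue
                    v[free] = sol
                elif np.max(np.abs(rhs)) > tol:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                val = float(c @ v)
                if best is None or val > best:
                    best = val
    return best


def random_network(rng, max_reactions=6):
    """A random bounded stoichiometric network as a MetabolicModel."""
    n = int(rng.integers(2, max_reactions + 1))
    m = int(rng.integers(1, n))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        mask = rng.random((m, n)) < 0.4
        S[mask] = 0.0
        if np.any(S):
            break
    lb = np.where(rng.random(n) < 0.5, -rng.integers(1, 11, n), 0).astype(float)
    ub = rng.integers(0, 11, n).astype(float)
    objective = np.zeros(n)
    objective[0] = 1.0
    return MetabolicModel(
        species_id="rand",
        metabolite_ids=[f"m{i}" for i in range(m)],
        reaction_ids=[f"r{j}" for j in range(n)],
        S=S, lb=lb, ub=ub, objective=objective,
        biomass_reaction="r0",
    )


@pytest.fixture
def glucose_toy():
    """The 3-metabolite toy: uptake EX_glc (lb = -10), glc -> 0.5 biomass,
    biomass sink.  Maximal growth rate is 5 by construction."""
    return MetabolicModel(
        species_id="toy",
        metabolite_ids=["glc", "bio"],
        reaction_ids=["EX_glc", "CONV", "BIOMASS"],
        S=np.array([[-1.0, -1.0, 0.0],
                    [0.0, 0.5, -1.0]]),
        lb=np.array([-10.0, 0.0, 0.0]),
        ub=np.array([0.0, 1000.0, 1000.0]),
        objective=np.array([0.0, 0.0, 1.0]),
        biomass_reaction="BIOMASS",
        exchange_map={"EX_glc": "glc"},
    )


@pytest.fixture
def parallel_pathways():
    """Two routes from substrate to biomass with equal yield: the direct
    reaction and a two-step detour.  The FBA optimum is degenerate; the
    parsimonious solution routes everything through the direct reaction."""
    return MetabolicModel(
        species_id="twopath",
        metabolite_ids=["a", "b", "bio"],
        reaction_ids=["EX_a", "DIRECT", "DETOUR1", "DETOUR2", "BIOMASS"],
        S=np.array([
            [-1.0, -1.0, -1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, -1.0, 0.0],
            [0.0, 1.0, 0.0, 1.0, -1.0],
        ]),
        lb=np.array([-4.0, 0.0, 0.0, 0.0, 0.0]),
        ub=np.array([0.0, 100.0, 100.0, 100.0, 100.0]),
        objective=np.array([0.0, 0.0, 0.0, 0.0, 1.0]),
        biomass_reaction="BIOMASS",
        exchange_map={"EX_a": "a"},
    )


@pytest.fixture
def community3():
    """3 species competing for one carbon source (no cross-feeding)."""
    com = generate_community(3, cross_feeding=False, seed=0)
    reactor = ReactorConfig(c0=dict(com.medium))
    return com, reactor


@pytest.fixture
def community4x():
    """4 species with a cross-feeding chain."""
    com = generate_community(4, cross_feeding=True, seed=0)
    reactor = ReactorConfig(c0=dict(com.medium))
    return com, reactor
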