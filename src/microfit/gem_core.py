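"""Stoichiometric model container and steady-state flux balance analysis.

The inner linear program of the community simulator: for one species at one
time step, maximize the biomass objective subject to the quasi-steady-state
constraint ``S v = 0`` and flux bounds.  Exchange fluxes follow the usual sign
convention: negative = uptake from the environment, positive = secretion.

Infeasibility is a *value* here, not an exception — during a dynamic
simulation a species may transiently be unable to grow (e.g. its sole carbon
source is exhausted) and the stepper must carry on with zero fluxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: max allowed |S v| for a solution to count as steady state
STEADY_STATE_TOL = 1e-6
#: max allowed bound violation
BOUND_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a MetabolicModel violates its structural invariants."""


@dataclass
class MetabolicModel:
    """Stoichiometric reconstruction of a single species.

    Parameters
    ----------
    species_id : str
        Identifier of the organism.
    metabolite_ids, reaction_ids : list of str
        Row and column labels of ``S``.
    S : ndarray, shape (n_metabolites, n_reactions)
        Stoichiometric coefficients (dimensionless).
    lb, ub : ndarray, shape (n_reactions,)
        Default flux bounds in mmol/gDW/h.
    objective : ndarray, shape (n_reactions,)
        Linear objective coefficients; by convention +1 on the biomass
        reaction and 0 elsewhere, and the LP *maximizes* it.
    biomass_reaction : str
        Reaction whose flux is the specific growth rate mu (1/h).
    exchange_map : dict
        exchange reaction id -> shared-pool compound id.  Only reactions in
        this map exchange mass with the community pool.
    """

    species_id: str
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective: np.ndarray
    biomass_reaction: str
    exchange_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (m, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        for name, vec in (("lb", self.lb), ("ub", self.ub),
                          ("objective", self.objective)):
            if vec.shape != (n,):
                raise ModelValidationError(f"{name} must have length {n}")
        if np.any(self.lb > self.ub):
            raise ModelValidationError("lb > ub for some reaction")
        if self.biomass_reaction not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in model"
            )
        for rxn in self.exchange_map:
            if rxn not in self._rxn_index:
                raise ModelValidationError(f"exchange reaction {rxn!r} not in model")
            # exchanges cross the system boundary: one metabolite involved
            col = self.S[:, self._rxn_index[rxn]]
            if np.count_nonzero(col) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn!r} must touch exactly one metabolite"
                )

    # -- helpers ----------------------------------------------------------
    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(
                f"reaction {rxn_id!r} not in model {self.species_id!r}"
            ) from None

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def uptake_exchanges(self) -> list[str]:
        """Exchange reactions whose default bounds permit uptake (lb < 0)."""
        return [r for r in self.exchange_map
                if self.lb[self._rxn_index[r]] < 0]


@dataclass
class FBASolution:
    """Outcome of one FBA solve."""

    status: str  # 'optimal' | 'infeasible' | 'unbounded'
    fluxes: np.ndarray
    growth_rate: float
    objective_value: float

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _apply_overrides(
    model: MetabolicModel,
    bound_overrides: Mapping[str, tuple[float, float]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    lb = model.lb.copy()
    ub = model.ub.copy()
    if bound_overrides:
        for rxn, (lo, hi) in bound_overrides.items():
            i = model.reaction_index(rxn)  # raises naming the id
            if lo > hi:
                raise ValueError(
                    f"override for {rxn!r} has lb {lo} > ub {hi}"
                )
            lb[i], ub[i] = lo, hi
    return lb, ub


def solve_fba(
    model: MetabolicModel,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FBASolution:
    """Maximize ``objective . v`` subject to ``S v = 0`` and flux bounds.

    ``bound_overrides`` maps reaction ids to replacement ``(lb, ub)`` pairs,
    used by the dynamic stepper to impose Monod uptake limits.

    An infeasible program returns ``status='infeasible'`` with zero fluxes
    rather than raising, so that non-growth is an ordinary simulator state.
    """
    lb, ub = _apply_overrides(model, bound_overrides)
    n = model.n_reactions
    res = linprog(
        c=-model.objective,
        A_eq=model.S,
        b_eq=np.zeros(len(model.metabolite_ids)),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    bio = model.reaction_index(model.biomass_reaction)
    if res.status == 0:
        v = np.asarray(res.x, dtype=float)
        return FBASolution("optimal", v, float(v[bio]), float(-res.fun))
    status = "unbounded" if res.status == 3 else "infeasible"
    zeros = np.zeros(n)
    return FBASolution(status, zeros, 0.0, 0.0)


def resolve_unique_flux(
    model: MetabolicModel,
    solution: FBASolution,
    bound_overrides: Mapping[str, tuple[float, float]] | None = None,
) -> FBASolution:
    """Pick a canonical flux vector among alternate optima (parsimonious FBA).

    Re-solves minimizing the total absolute flux ``sum |v|`` with the
    objective pinned at its optimum, making repeated solves of the same
    problem reproducible.  If the secondary program fails numerically the
    input solution is returned unchanged with a warning.
    """
    if not solution.optimal:
        raise ValueError("resolve_unique_flux requires an optimal input solution")
    lb, ub = _apply_overrides(model, bound_overrides)
    n = model.n_reactions
    m = len(model.metabolite_ids)
    # variables z = [v, t]; minimize sum t  s.t.  S v = 0, obj.v >= opt - tol,
    # -t <= v <= t, lb <= v <= ub, t >= 0.  The optimum is held by an
    # inequality slightly below the reported value: a hard equality is
    # routinely infeasible at solver precision.
    opt_tol = 1e-9 + 1e-9 * abs(solution.objective_value)
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.zeros((m, 2 * n))
    A_eq[:, :n] = model.S
    b_eq = np.zeros(m)
    eye = np.eye(n)
    obj_row = np.concatenate([-model.objective, np.zeros(n)])
    A_ub = np.vstack([
        np.block([[eye, -eye], [-eye, -eye]]),  # v - t <= 0 ; -v - t <= 0
        obj_row,                                # -obj.v <= -(opt - tol)
    ])
    b_ub = np.concatenate([np.zeros(2 * n),
                           [-(solution.objective_value - opt_tol)]])
    t_max = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + list(zip(np.zeros(n), t_max))
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        logger.warning(
            "parsimonious re-solve failed for %s (status %s); "
            "keeping primary solution", model.species_id, res.status,
        )
        return solution
    v = np.asarray(res.x[:n], dtype=float)
    bio = model.reaction_index(model.biomass_reaction)
    return FBASolution("optimal", v, float(v[bio]),
                       float(model.objective @ v))


class IncrementalFBA:
    """Persistent LP for one species, re-solved many times with new bounds.

    The dynamic simulator solves the same FBA problem thousands of times per
    run with only the Monod uptake bounds changing, so the problem is built
    once in GLPK (via swiglpk, pulled in by cobrapy) and each call merely
    updates column bounds and warm-starts the simplex.  Results agree with
    :func:`solve_fba` / :func:`resolve_unique_flux` to solver tolerance;
    if swiglpk is unavailable those routines are used directly.

    The wrapped model is treated as immutable after construction.
    """

    def __init__(self, model: MetabolicModel, parsimonious: bool = True):
        self.model = model
        self.parsimonious = parsimonious
        try:
            import swiglpk as glp
        except ImportError:  # pragma: no cover - swiglpk ships with cobra
            glp = None
        self._glp = glp
        if glp is None:
            return
        n = model.n_reactions
        m = len(model.metabolite_ids)
        # primary problem: maximize obj.v, S v = 0
        self._prob = self._build(glp, model, with_abs=False)
        # secondary (parsimonious): minimize sum t over [v, t]
        self._pprob = self._build(glp, model, with_abs=True) if parsimonious else None
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        self._parm = parm
        self._n, self._m = n, m

    @staticmethod
    def _build(glp, model: MetabolicModel, with_abs: bool):
        n = model.n_reactions
        m = len(model.metabolite_ids)
        prob = glp.glp_create_prob()
        ncols = 2 * n if with_abs else n
        nrows = (m + n + 1) if with_abs else m
        glp.glp_add_rows(prob, nrows)
        glp.glp_add_cols(prob, ncols)
        entries: list[tuple[int, int, float]] = []
        for i in range(m):
            glp.glp_set_row_bnds(prob, i + 1, glp.GLP_FX, 0.0, 0.0)
        for (i, j) in zip(*np.nonzero(model.S)):
            entries.append((int(i) + 1, int(j) + 1, float(model.S[i, j])))
        if with_abs:
            # |v_j| <= t_j as two one-sided rows: v - t <= 0 (rows m+1..m+n)
            # and v + t >= 0 (rows m+n+2..m+2n+1); row m+n+1 pins the
            # primary objective, its bound is refreshed on every solve.
            glp.glp_add_rows(prob, n)
            for j in range(n):
                entries.append((m + 1 + j, j + 1, 1.0))
                entries.append((m + 1 + j, n + j + 1, -1.0))
                glp.glp_set_row_bnds(prob, m + 1 + j, glp.GLP_UP, 0.0, 0.0)
                entries.append((m + n + 1 + j + 1, j + 1, 1.0))
                entries.append((m + n + 1 + j + 1, n + j + 1, 1.0))
                glp.glp_set_row_bnds(prob, m + n + 1 + j + 1, glp.GLP_LO, 0.0, 0.0)
            # objective-pin row (index m + n + 1): obj.v >= opt - tol
            for j in np.flatnonzero(model.objective):
                entries.append((m + n + 1, int(j) + 1, float(model.objective[j])))
            glp.glp_set_row_bnds(prob, m + n + 1, glp.GLP_LO, 0.0, 0.0)
            for j in range(n):
                glp.glp_set_obj_coef(prob, n + j + 1, 1.0)
            glp.glp_set_obj_dir(prob, glp.GLP_MIN)
        else:
            for j in range(n):
                glp.glp_set_obj_coef(prob, j + 1, float(model.objective[j]))
            glp.glp_set_obj_dir(prob, glp.GLP_MAX)
        ia = glp.intArray(len(entries) + 1)
        ja = glp.intArray(len(entries) + 1)
        ar = glp.doubleArray(len(entries) + 1)
        for k, (i, j, a) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = i, j, a
        glp.glp_load_matrix(prob, len(entries), ia, ja, ar)
        return prob

    def _set_col(self, prob, j: int, lo: float, hi: float) -> None:
        glp = self._glp
        if lo == hi:
            glp.glp_set_col_bnds(prob, j, glp.GLP_FX, lo, hi)
        elif np.isinf(lo) and np.isinf(hi):
            glp.glp_set_col_bnds(prob, j, glp.GLP_FR, 0.0, 0.0)
        elif np.isinf(lo):
            glp.glp_set_col_bnds(prob, j, glp.GLP_UP, 0.0, hi)
        elif np.isinf(hi):
            glp.glp_set_col_bnds(prob, j, glp.GLP_LO, lo, 0.0)
        else:
            glp.glp_set_col_bnds(prob, j, glp.GLP_DB, lo, hi)

    def solve(
        self,
        bound_overrides: Mapping[str, tuple[float, float]] | None = None,
    ) -> FBASolution:
        if self._glp is None:  # fallback: reference implementations
            sol = solve_fba(self.model, bound_overrides)
            if sol.optimal and self.parsimonious:
                sol = resolve_unique_flux(self.model, sol, bound_overrides)
            return sol
        glp = self._glp
        model = self.model
        lb, ub = _apply_overrides(model, bound_overrides)
        n = self._n
        for j in range(n):
            self._set_col(self._prob, j + 1, float(lb[j]), float(ub[j]))
        ret = glp.glp_simplex(self._prob, self._parm)
        status = glp.glp_get_status(self._prob) if ret == 0 else None
        if status != glp.GLP_OPT:
            kind = "unbounded" if status == glp.GLP_UNBND else "infeasible"
            return FBASolution(kind, np.zeros(n), 0.0, 0.0)
        v = np.array([glp.glp_get_col_prim(self._prob, j + 1) for j in range(n)])
        opt = float(model.objective @ v)
        bio = model.reaction_index(model.biomass_reaction)
        if not self.parsimonious:
            return FBASolution("optimal", v, float(v[bio]), opt)
        # parsimonious pass
        pp = self._pprob
        for j in range(n):
            self._set_col(pp, j + 1, float(lb[j]), float(ub[j]))
            t_hi = max(abs(float(lb[j])), abs(float(ub[j])))
            self._set_col(pp, n + j + 1, 0.0, t_hi)
        tol = 1e-9 + 1e-9 * abs(opt)
        glp.glp_set_row_bnds(pp, self._m + self._n + 1, glp.GLP_LO, opt - tol, 0.0)
        ret = glp.glp_simplex(pp, self._parm)
        if ret != 0 or glp.glp_get_status(pp) != glp.GLP_OPT:
            logger.warning(
                "parsimonious re-solve failed for %s; keeping primary solution",
                model.species_id,
            )
            return FBASolution("optimal", v, float(v[bio]), opt)
        v2 = np.array([glp.glp_get_col_prim(pp, j + 1) for j in range(n)])
        return FBASolution("optimal", v2, float(v2[bio]),
                           float(model.objective @ v2))
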