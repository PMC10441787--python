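"""Readers and writers for every on-disk artifact.

Formats: SBML Level 3 + fbc for metabolic models (via cobrapy), plain TSV
for medium tables, abundance profiles, grouping files, trajectories and
cycle logs, and YAML or JSON for run configuration.  All round trips are
value-preserving; loaders never silently drop rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import ReactorConfig, Trajectory
from .fitting import AbundanceProfile, FitConfig, FitResult
from .gem_core import MetabolicModel
from .hierarchy import GroupingScheme

logger = logging.getLogger(__name__)

#: significant digits used by every TSV writer (round-trip safe)
FLOAT_FMT = "%.12g"


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr for the command-line tools."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# SBML models (cobrapy behind the scenes)
# ---------------------------------------------------------------------------

def model_to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (exchange metabolites in compartment 'e')."""
    import cobra

    cm = cobra.Model(model.species_id)
    exchanged = {int(np.flatnonzero(model.S[:, model.reaction_index(r)])[0])
                 for r in model.exchange_map}
    mets = {}
    for i, mid in enumerate(model.metabolite_ids):
        comp = "e" if i in exchanged else "c"
        mets[mid] = cobra.Metabolite(mid, compartment=comp)
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        cm.add_reactions([rxn])
        rxn.add_metabolites({
            mets[model.metabolite_ids[i]]: float(model.S[i, j])
            for i in np.flatnonzero(model.S[:, j])
        })
    cm.objective = {
        cm.reactions.get_by_id(rid): float(model.objective[j])
        for j, rid in enumerate(model.reaction_ids)
        if model.objective[j] != 0
    }
    return cm


def model_from_cobra(cm, exchange_prefix: str = "EX_") -> MetabolicModel:
    """Convert a cobra.Model; exchanges are recognized by single-metabolite
    stoichiometry or the id prefix, and mapped to their metabolite's id."""
    metabolite_ids = [m.id for m in cm.metabolites]
    reaction_ids = [r.id for r in cm.reactions]
    mindex = {m: i for i, m in enumerate(metabolite_ids)}
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    lb = np.zeros(len(reaction_ids))
    ub = np.zeros(len(reaction_ids))
    objective = np.zeros(len(reaction_ids))
    exchange_map: dict[str, str] = {}
    biomass = None
    for j, rxn in enumerate(cm.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        coef = rxn.objective_coefficient
        objective[j] = coef
        if coef:
            biomass = rxn.id
        for met, s in rxn.metabolites.items():
            S[mindex[met.id], j] = s
        # the biomass sink is single-metabolite too; objective carriers are
        # never exchanges
        if len(rxn.metabolites) == 1 and not coef and (
                rxn.id.startswith(exchange_prefix) or rxn.boundary):
            exchange_map[rxn.id] = next(iter(rxn.metabolites)).id
    if biomass is None:
        raise ValueError(f"model {cm.id!r} has no objective (biomass) reaction")
    return MetabolicModel(
        species_id=cm.id or "model",
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S, lb=lb, ub=ub, objective=objective,
        biomass_reaction=biomass,
        exchange_map=exchange_map,
    )


def read_sbml_model(path: str | Path, exchange_prefix: str = "EX_") -> MetabolicModel:
    """Load one species model from SBML L3 + fbc."""
    from cobra.io import read_sbml_model as _read

    cm = _read(str(path))
    model = model_from_cobra(cm, exchange_prefix=exchange_prefix)
    if not model.species_id or model.species_id == "model":
        model.species_id = Path(path).stem
    return model


def write_sbml_model(model: MetabolicModel, path: str | Path) -> None:
    from cobra.io import write_sbml_model as _write

    _write(model_to_cobra(model), str(path))


def load_models_dir(path: str | Path, exchange_prefix: str = "EX_") -> list[MetabolicModel]:
    """Load every ``*.xml``/``*.sbml`` in a directory, sorted by filename."""
    files = sorted(p for p in Path(path).iterdir()
                   if p.suffix.lower() in (".xml", ".sbml"))
    if not files:
        raise FileNotFoundError(f"no SBML files in {path}")
    return [read_sbml_model(p, exchange_prefix) for p in files]


# ---------------------------------------------------------------------------
# medium / diet tables
# ---------------------------------------------------------------------------

def load_medium(path: str | Path, volume: float = 1.0) -> dict[str, float]:
    """Read a medium table to per-compound concentrations in mM.

    Expected TSV columns: ``compound``, ``amount``, ``unit`` (one of mM,
    mmol, mg) and, for mg rows, ``mw`` (g/mol).  mg amounts convert via
    mmol = mg / MW; mmol amounts divide by the culture volume.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"compound", "amount", "unit"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"medium table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        compound = str(row["compound"])
        amount = float(row["amount"])
        unit = str(row["unit"]).strip()
        if amount < 0:
            raise ValueError(f"negative amount for {compound!r}")
        if unit == "mM":
            conc = amount
        elif unit == "mmol":
            conc = amount / volume
        elif unit == "mg":
            mw = row.get("mw", np.nan)
            if pd.isna(mw):
                raise ValueError(
                    f"compound {compound!r} given in mg but has no molecular weight"
                )
            conc = amount / float(mw) / volume
        else:
            raise ValueError(f"unknown unit {unit!r} for {compound!r}")
        if compound in out:
            raise ValueError(f"duplicate medium compound {compound!r}")
        out[compound] = conc
    return out


def write_medium(medium: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        {"compound": list(medium), "amount": list(medium.values()),
         "unit": "mM"}
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# abundance profiles and grouping files
# ---------------------------------------------------------------------------

def load_abundance(path: str | Path) -> AbundanceProfile:
    """Read a two-column (species, value) table; values may be fractions,
    percentages or counts — they are renormalized to sum to 1 (logged)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("abundance table needs two columns: species, value")
    species = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 1].astype(float).to_numpy()
    if np.any(values < 0):
        bad = species[int(np.flatnonzero(values < 0)[0])]
        raise ValueError(f"negative abundance for {bad!r}")
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise ValueError(f"duplicate species in abundance table: {dupes}")
    total = values.sum()
    if total <= 0:
        raise ValueError("abundance table sums to zero")
    if abs(total - 1.0) > 1e-9:
        logger.info("renormalizing abundance values (sum %.6g) to fractions", total)
    return AbundanceProfile(tuple(species), values / total)


def write_abundance(profile: AbundanceProfile, path: str | Path) -> None:
    pd.DataFrame({
        "species": profile.species_ids,
        "fraction": profile.fractions,
    }).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_grouping(path: str | Path) -> GroupingScheme:
    """Read a (species_id, group_label) table; group order follows first
    appearance of each label."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("grouping table needs two columns: species, group")
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row.iloc[1]), []).append(str(row.iloc[0]))
    return GroupingScheme(
        groups=[tuple(v) for v in groups.values()],
        labels=list(groups),
    )


def write_grouping(grouping: GroupingScheme, path: str | Path) -> None:
    rows = [(sp, label)
            for label, group in zip(grouping.labels, grouping.groups)
            for sp in group]
    pd.DataFrame(rows, columns=["species", "group"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trajectories and cycle logs
# ---------------------------------------------------------------------------

def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    compounds: Sequence[str] | None = None,
    flux_path: str | Path | None = None,
) -> None:
    """Write the state trajectory as TSV: t, one X_ column per species and
    one C_ column per (selected) compound.

    ``compounds`` restricts the concentration columns (an empty list keeps
    biomass only).  ``flux_path`` additionally writes the per-step realized
    growth rates and specific exchange fluxes.
    """
    if compounds is None:
        selected = list(traj.compound_ids)
    else:
        unknown = [c for c in compounds if c not in traj.compound_ids]
        if unknown:
            raise ValueError(f"unknown compounds in selection: {unknown}")
        selected = list(compounds)
    idx = [traj.compound_ids.index(c) for c in selected]
    data: dict[str, np.ndarray] = {"t": traj.times()}
    X = traj.biomass()
    C = traj.concentrations()
    for j, sp in enumerate(traj.species_ids):
        data[f"X_{sp}"] = X[:, j]
    for c, i in zip(selected, idx):
        data[f"C_{c}"] = C[:, i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    if flux_path is not None:
        rows = []
        for k, rec in enumerate(traj.records):
            t = traj.states[k].t
            for j, sp in enumerate(traj.species_ids):
                row = {"t": t, "species": sp,
                       "growth_rate": rec.growth_rates[j]}
                for c, i in zip(selected, idx):
                    row[f"v_{c}"] = rec.pool_fluxes[j, i]
                    row[f"limiting_{c}"] = int(rec.limiting[j, i])
                rows.append(row)
        pd.DataFrame(rows).to_csv(flux_path, sep="\t", index=False,
                                  float_format=FLOAT_FMT)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory TSV back as a DataFrame (t, X_*, C_* columns)."""
    return pd.read_csv(path, sep="\t")


def write_cycle_log(result: FitResult, path: str | Path) -> None:
    """One row per fitting cycle: J, per-species fraction and mean Vmax."""
    rows = []
    for k in range(result.n_cycles):
        row: dict[str, float] = {"cycle": k + 1, "J": result.j_history[k]}
        for i, sp in enumerate(result.species_ids):
            row[f"frac_{sp}"] = result.fraction_history[k][i]
        vmax = result.vmax_history[k]
        for sp in result.species_ids:
            vals = [v for (s, _), v in vmax.items() if s == sp]
            row[f"vmax_{sp}"] = float(np.mean(vals)) if vals else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def save_config(
    path: str | Path,
    reactor: ReactorConfig,
    fit_config: FitConfig,
) -> None:
    """Dump every reactor and fitting setting so a run is reproducible from
    config + input files.  YAML unless the path ends in .json."""
    payload = {
        "reactor": _plain(asdict(reactor)),
        "fit": _plain(asdict(fit_config)),
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path: str | Path) -> tuple[ReactorConfig, FitConfig]:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    payload = payload or {}
    reactor_kw = dict(payload.get("reactor", {}))
    if "frozen_species" in reactor_kw:
        reactor_kw["frozen_species"] = tuple(reactor_kw["frozen_species"])
    known = {f.name for f in fields(ReactorConfig)}
    unknown = set(reactor_kw) - known
    if unknown:
        raise ValueError(f"unknown reactor settings: {sorted(unknown)}")
    fit_kw = dict(payload.get("fit", {}))
    known = {f.name for f in fields(FitConfig)}
    unknown = set(fit_kw) - known
    if unknown:
        raise ValueError(f"unknown fit settings: {sorted(unknown)}")
    return ReactorConfig(**reactor_kw), FitConfig(**fit_kw)


def _plain(obj):
    """Recursively convert numpy / tuple values to YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
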