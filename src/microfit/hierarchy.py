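"""Hierarchical group-split fitting for wide-dynamic-range profiles.

When reference fractions span orders of magnitude, rare species lose the
competition for substrate during a joint simulation and the optimizer cannot
recover them.  The hierarchical strategy splits the profile into groups of
comparable abundance, renormalizes each group to sum to 1, fits every group
as its own community on a fresh copy of the medium, and merges the fitted
group fractions back together weighted by each group's share of the original
profile.  Cross-group metabolic interactions are dropped by construction;
compounds exchanged by species in more than one group are reported so the
user can judge whether that matters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import KineticParams, ReactorConfig
from .fitting import AbundanceProfile, FitConfig, FitResult, community_fractions, fit
from .gem_core import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass
class GroupingScheme:
    """Ordered partition of the profile's species into disjoint groups."""

    groups: list[tuple[str, ...]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.groups = [tuple(g) for g in self.groups]
        if not self.labels:
            self.labels = [f"group{i + 1}" for i in range(len(self.groups))]
        if len(self.labels) != len(self.groups):
            raise ValueError("one label per group required")
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty group in grouping scheme")
            overlap = seen & set(g)
            if overlap:
                raise ValueError(f"species in more than one group: {sorted(overlap)}")
            seen |= set(g)

    def species(self) -> set[str]:
        return {sp for g in self.groups for sp in g}

    def validate_for(self, profile: AbundanceProfile) -> None:
        missing = set(profile.species_ids) - self.species()
        if missing:
            raise ValueError(f"species missing from grouping: {sorted(missing)}")
        extra = self.species() - set(profile.species_ids)
        if extra:
            raise ValueError(f"grouping names unknown species: {sorted(extra)}")


@dataclass
class HierarchicalResult:
    """Per-group fits plus the merged community profile."""

    group_results: list[FitResult | None]
    group_errors: list[str | None]
    merged_fractions: AbundanceProfile
    shares: list[float]
    grouping: GroupingScheme


def auto_grouping(profile: AbundanceProfile) -> GroupingScheme:
    """Default grouping: bin species by the order of magnitude of f_ref.

    Species with equal ``floor(log10 f)`` share a group; zero fractions go
    to the rarest bin.  A uniform profile therefore yields a single group.
    """
    mags: dict[int, list[str]] = {}
    nonzero = profile.fractions[profile.fractions > 0]
    floor_mag = int(math.floor(math.log10(nonzero.min()))) if len(nonzero) else 0
    for sp, f in zip(profile.species_ids, profile.fractions):
        mag = int(math.floor(math.log10(f))) if f > 0 else floor_mag
        mags.setdefault(mag, []).append(sp)
    ordered = sorted(mags.items(), key=lambda kv: -kv[0])  # abundant first
    return GroupingScheme(
        groups=[tuple(sps) for _, sps in ordered],
        labels=[f"1e{mag}" for mag, _ in ordered],
    )


def split_profile(
    profile: AbundanceProfile, grouping: GroupingScheme
) -> tuple[list[AbundanceProfile], list[float]]:
    """Renormalized per-group sub-profiles plus each group's original share."""
    grouping.validate_for(profile)
    subs: list[AbundanceProfile] = []
    shares: list[float] = []
    for g in grouping.groups:
        f = np.array([profile.fraction_of(sp) for sp in g])
        share = float(f.sum())
        if share <= 0:
            raise ValueError(
                f"group {g} has zero total reference abundance; cannot renormalize"
            )
        subs.append(AbundanceProfile(g, f / share))
        shares.append(share)
    return subs, shares


def merge_groups(
    group_fractions: Sequence[AbundanceProfile], shares: Sequence[float]
) -> AbundanceProfile:
    """Weight each group's fractions by its share and concatenate."""
    if len(group_fractions) != len(shares):
        raise ValueError("one share per group required")
    if abs(sum(shares) - 1.0) > 1e-9:
        raise ValueError(f"shares sum to {sum(shares):.12g}, expected 1")
    ids: list[str] = []
    fracs: list[float] = []
    for sub, share in zip(group_fractions, shares):
        ids.extend(sub.species_ids)
        fracs.extend((share * sub.fractions).tolist())
    return AbundanceProfile(tuple(ids), np.array(fracs))


def shared_compounds(
    models: Sequence[MetabolicModel], grouping: GroupingScheme
) -> set[str]:
    """Pool compounds exchanged by species in more than one group."""
    by_sp = {m.species_id: set(m.exchange_map.values()) for m in models}
    per_group = [
        set().union(*(by_sp.get(sp, set()) for sp in g)) for g in grouping.groups
    ]
    shared: set[str] = set()
    for i, a in enumerate(per_group):
        for b in per_group[i + 1:]:
            shared |= a & b
    return shared


def fit_hierarchical(
    models: Sequence[MetabolicModel],
    profile: AbundanceProfile,
    grouping: GroupingScheme,
    params0: KineticParams,
    reactor: ReactorConfig,
    config: FitConfig,
) -> HierarchicalResult:
    """Fit every group independently, then merge fractions by group share.

    Each group is simulated as its own community over a fresh copy of the
    medium.  A failure in one group is recorded and the remaining groups are
    still fitted; failed groups contribute their renormalized *reference*
    fractions to the merge so the merged vector stays a valid profile.
    """
    grouping.validate_for(profile)
    by_id = {m.species_id: m for m in models}
    missing = grouping.species() - set(by_id)
    if missing:
        raise ValueError(f"no model for species: {sorted(missing)}")
    shared = shared_compounds(models, grouping)
    if shared:
        logger.info(
            "compounds exchanged across groups (interactions dropped by the "
            "split): %s", ", ".join(sorted(shared)),
        )
    subs, shares = split_profile(profile, grouping)
    results: list[FitResult | None] = []
    errors: list[str | None] = []
    fitted: list[AbundanceProfile] = []
    for label, sub in zip(grouping.labels, subs):
        group_models = [by_id[sp] for sp in sub.species_ids]
        sub_params = KineticParams(
            vmax={k: v for k, v in params0.vmax.items()
                  if k[0] in sub.species_ids},
            ks=params0.ks, xmax=params0.xmax,
        )
        try:
            res = fit(group_models, sub, sub_params, reactor, config)
        except Exception as exc:  # noqa: BLE001 - isolate per-group failures
            logger.error("group %s failed: %s", label, exc)
            results.append(None)
            errors.append(str(exc))
            fitted.append(sub)
            continue
        results.append(res)
        errors.append(None)
        # fractions of the best cycle (the trajectory kept in the result)
        fitted.append(AbundanceProfile(
            sub.species_ids, community_fractions(res.final_trajectory.final.X)))
    merged = merge_groups(fitted, shares)
    return HierarchicalResult(results, errors, merged, shares, grouping)
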