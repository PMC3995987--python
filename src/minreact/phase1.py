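"""Flux-balance LPs and Phase-1 classification of reaction groups.

Phase 1 sorts dependency groups into three bins with respect to the biomass
target:

* essential (SRG)  — deactivating the group makes the target infeasible;
  these groups appear in every minimal reaction set;
* extraneous (XRG) — no member can carry any flux in any steady state that
  meets the target (flux range (0, 0) under the biomass floor); these
  appear in no minimal set and are fixed to zero;
* indeterminate (IRG) — everything else; the substitutable reactions that
  generate multiple optima, handed to the Phase-2 MILP.

Both tests are functional (deletion LP / flux-variability LP), so a group
is never placed in essential or extraneous unless the classification is
provable; anything unresolved stays indeterminate and is settled by the
MILP, which keeps the enumerated solution set exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .grouping import ReactionGroup
from .network import FluxVector, MetabolicNetwork

__all__ = [
    "InfeasibleProblemError",
    "GroupClassification",
    "max_biomass_lp",
    "flux_range",
    "classify_groups",
]

#: Slack on biomass-target comparisons (mmol-scale fluxes).
TARGET_TOL = 1e-6

#: Absolute flux-range tolerance below which a reaction counts as blocked.
ZERO_FLUX_TOL = 1e-9


class InfeasibleProblemError(RuntimeError):
    """The LP/MILP has no feasible point (distinct from a zero optimum)."""


@dataclass(frozen=True)
class GroupClassification:
    essential: frozenset[int]
    extraneous: frozenset[int]
    indeterminate: frozenset[int]
    forced_essential_overrides: frozenset[str] = frozenset()

    def __post_init__(self):
        for a, b in (
            (self.essential, self.extraneous),
            (self.essential, self.indeterminate),
            (self.extraneous, self.indeterminate),
        ):
            if a & b:
                raise ValueError("classification sets must be disjoint")


def _lp_arrays(net: MetabolicNetwork, inactive: Iterable[str] = ()):
    S = net.stoichiometric_matrix(internal_only=True)
    inactive = set(inactive)
    bounds = [
        (0.0, 0.0) if r.id in inactive else (r.lb, r.ub) for r in net.reactions
    ]
    return S, bounds


def max_biomass_lp(
    net: MetabolicNetwork, inactive: Iterable[str] = ()
) -> tuple[float, FluxVector]:
    """Maximize biomass flux subject to S.v = 0, bounds, and v_j = 0 for
    every reaction in ``inactive``.

    Raises :class:`InfeasibleProblemError` when no steady state exists at
    all, which is distinct from a feasible problem with zero optimum.
    """
    inactive = set(inactive)
    unknown = inactive - set(net.reaction_ids)
    if unknown:
        raise ValueError(f"inactive set contains unknown reactions {sorted(unknown)}")
    S, bounds = _lp_arrays(net, inactive)
    c = np.zeros(net.n_reactions)
    c[net.reaction_position(net.biomass_reaction.id)] = -1.0
    res = linprog(c, A_eq=S if S.size else None, b_eq=np.zeros(S.shape[0]) if S.size else None,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleProblemError("steady-state LP infeasible")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    flux = FluxVector({r.id: float(v) for r, v in zip(net.reactions, res.x)})
    return float(-res.fun), flux


def flux_range(
    net: MetabolicNetwork,
    reaction: str,
    biomass_floor: float = 0.0,
    inactive: Iterable[str] = (),
) -> tuple[float, float]:
    """Flux-variability bounds of one reaction: min/max of v_reaction over
    S.v = 0, bounds, and v_biomass >= biomass_floor."""
    S, bounds = _lp_arrays(net, inactive)
    j = net.reaction_position(reaction)
    A_ub = np.zeros((1, net.n_reactions))
    A_ub[0, net.reaction_position(net.biomass_reaction.id)] = -1.0
    b_ub = np.array([-biomass_floor])
    out = []
    for sense in (1.0, -1.0):
        c = np.zeros(net.n_reactions)
        c[j] = sense
        res = linprog(c, A_ub=A_ub, b_ub=b_ub,
                      A_eq=S if S.size else None,
                      b_eq=np.zeros(S.shape[0]) if S.size else None,
                      bounds=bounds, method="highs")
        if res.status == 2:
            raise InfeasibleProblemError(
                f"flux_range infeasible at biomass floor {biomass_floor}"
            )
        if not res.success:
            raise RuntimeError(f"LP solver failure: {res.message}")
        out.append(float(sense * res.fun))
    return out[0], out[1]


def classify_groups(
    net: MetabolicNetwork,
    groups: Sequence[ReactionGroup],
    biomass_target: float | None = None,
    forced_essential_reactions: Iterable[str] = (),
) -> GroupClassification:
    """Partition groups into essential / extraneous / indeterminate.

    A group is essential iff the deletion LP (all members inactive) cannot
    reach the biomass target; extraneous iff every member's flux range under
    the target floor is (0, 0) within tolerance. Reactions listed in
    ``forced_essential_reactions`` (a modeller's judgement, e.g. compartment
    transporters) promote their groups to essential unconditionally.
    """
    target = net.biomass_target if biomass_target is None else float(biomass_target)
    grouped = {r for g in groups for r in g.members}
    if grouped != set(net.reaction_ids):
        raise ValueError("groups do not partition the network's reactions")
    opt, _ = max_biomass_lp(net)
    if opt < target - TARGET_TOL:
        raise InfeasibleProblemError(
            f"network cannot reach biomass target {target} (max {opt:.6g})"
        )
    forced = frozenset(forced_essential_reactions)

    essential: set[int] = set()
    extraneous: set[int] = set()
    indeterminate: set[int] = set()
    for g in groups:
        if forced & set(g.members):
            essential.add(g.id)
            continue
        try:
            deleted_opt, _ = max_biomass_lp(net, inactive=g.members)
        except InfeasibleProblemError:
            deleted_opt = -np.inf
        if deleted_opt < target - TARGET_TOL:
            essential.add(g.id)
            continue
        blocked = True
        for rid in g.members:
            lo, hi = flux_range(net, rid, biomass_floor=target)
            if max(abs(lo), abs(hi)) > ZERO_FLUX_TOL:
                blocked = False
                break
        (extraneous if blocked else indeterminate).add(g.id)
    return GroupClassification(
        essential=frozenset(essential),
        extraneous=frozenset(extraneous),
        indeterminate=frozenset(indeterminate),
        forced_essential_overrides=forced,
    )
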