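"""Knockout-plan derivation for a chosen minimal reaction set.

Realizing a minimal reaction set in a strain does not require deleting
every complement reaction individually: deleting one reaction silences all
reactions dependent on it. The selection loop below walks the complement
in ascending depth order (input order on ties), picks the shallowest
remaining reaction as the next knockout, and drops from the worklist its
dependency-group co-members together with every reaction that can no
longer carry any steady-state flux once the knockouts so far are removed
(a flux-variability check on the reduced network, which also catches
cross-group cascades).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .andor import DepthMap
from .enumerator import MinimalReactionSet
from .grouping import ReactionGroup
from .network import MetabolicNetwork
from .phase1 import ZERO_FLUX_TOL, flux_range

__all__ = ["KnockoutPlan", "select_knockouts"]


@dataclass(frozen=True)
class KnockoutPlan:
    """Ordered deletions realizing one minimal set; ``covered`` maps each
    knockout to the complement reactions it silences for free."""

    minimal_set_id: int
    knockouts: tuple[str, ...]
    covered: dict[str, frozenset[str]]


def select_knockouts(
    net: MetabolicNetwork,
    minimal_set: MinimalReactionSet,
    depths: DepthMap,
    groups: Sequence[ReactionGroup],
    minimal_set_id: int = 0,
) -> KnockoutPlan:
    """Greedy lowest-depth-first knockout selection over the complement of
    the minimal set. Every complement reaction ends up either knocked out or
    covered by exactly one knockout."""
    group_of = {r: g for g in groups for r in g.members}
    order = {r.id: i for i, r in enumerate(net.reactions)}
    big = 1 << 30

    def key(rid: str) -> tuple[int, int]:
        return (depths.reaction_depth.get(rid, big), order[rid])

    remaining = sorted(
        (r for r in net.reaction_ids if r not in minimal_set.reactions), key=key
    )
    knockouts: list[str] = []
    covered: dict[str, frozenset[str]] = {}
    deleted: set[str] = set()

    while remaining:
        k = remaining[0]
        knockouts.append(k)
        deleted.add(k)
        dead = {
            r for r in group_of[k].members if r in remaining and r != k
        }
        # flux-based closure on the network minus everything deleted so far
        check = [r for r in remaining[1:] if r not in dead]
        inactive = deleted | dead
        for rid in check:
            lo, hi = flux_range(net, rid, biomass_floor=0.0, inactive=inactive)
            if max(abs(lo), abs(hi)) <= ZERO_FLUX_TOL:
                dead.add(rid)
        covered[k] = frozenset(dead)
        deleted |= dead
        remaining = [r for r in remaining if r not in deleted]
    return KnockoutPlan(
        minimal_set_id=minimal_set_id,
        knockouts=tuple(knockouts),
        covered=covered,
    )
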