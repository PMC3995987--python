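"""Grouping of linearly and flux-dependent reactions.

Two reactions are dependent when steady-state mass balance forces their
fluxes to be zero or nonzero together, so one binary variable per *group*
suffices in the minimal-reaction-set MILP. The structural certificate used
throughout is a shared internal metabolite with no alternative route: if
metabolite m has producers only inside a set of reactions and a single
consumer, deleting either side silences the other.

* linear dependency — a candidate reaction joins a group when at least one
  of its reactant metabolites is consumed only by the candidate and produced
  only by reactions already in the group;
* flux dependency — several reactions join together when each receives all
  of its reactants exclusively from one group member and is the sole
  consumer of each of them (e.g. a branch point whose two products feed two
  obligatory sinks).

Groups are grown breadth-first in depth order from the lowest-depth
ungrouped reaction, one depth layer at a time, stopping at the first layer
that contributes nothing; grouped reactions leave the worklist and the next
seed starts a new group. The result is a partition of the reaction set.
Exclusivity tests use the reversibility-aware producer/consumer sets, so a
reversible alternative route breaks exclusivity regardless of its nominal
direction (a too-fine group only costs solver time; a too-coarse one would
corrupt the enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .andor import AndOrGraph, DepthMap, build_and_or_graph
from .network import MetabolicNetwork

__all__ = [
    "ReactionGroup",
    "is_linearly_dependent",
    "find_flux_dependent",
    "group_reactions",
]

_UNREACHABLE_DEPTH = 1 << 30


@dataclass(frozen=True)
class ReactionGroup:
    """A maximal set of mutually flux-coupled reactions.

    ``norm`` (= member count) is the group's weight in the Phase-2
    objective; ``depth`` is the minimum member depth.
    """

    id: int
    members: tuple[str, ...]
    depth: int

    @property
    def norm(self) -> int:
        return len(self.members)

    def __contains__(self, rid: str) -> bool:
        return rid in self.members


def _coupling_metabolites(
    candidate: str, group: Iterable[str], graph: AndOrGraph
) -> list[str]:
    """Internal reactant metabolites of ``candidate`` whose sole consumer is
    the candidate and whose producers all lie in ``group``."""
    group = set(group)
    out = []
    for mid in graph.reactants(candidate):
        if not graph.is_connector(mid):
            continue
        if graph.effective_consumers(mid) != {candidate}:
            continue
        producers = graph.effective_producers(mid)
        if producers and producers <= group:
            out.append(mid)
    return out


def is_linearly_dependent(
    candidate: str,
    group: ReactionGroup | Iterable[str],
    net: MetabolicNetwork,
    graph: AndOrGraph | None = None,
) -> bool:
    """Whether ``candidate`` receives a reactant exclusively from ``group``.

    True iff some internal reactant of the candidate has the candidate as
    its only consumer and all of its producers inside the group — the
    single-producer/single-consumer chain pattern of a linear pathway.
    """
    graph = graph or build_and_or_graph(net)
    members = group.members if isinstance(group, ReactionGroup) else tuple(group)
    if candidate in members:
        raise ValueError(f"candidate {candidate!r} already in group")
    return bool(_coupling_metabolites(candidate, members, graph))


def find_flux_dependent(
    source: str,
    frontier: Iterable[str],
    net: MetabolicNetwork,
    graph: AndOrGraph | None = None,
) -> frozenset[str]:
    """Frontier reactions that must co-occur with ``source`` to balance its
    products.

    A frontier reaction qualifies when every one of its internal reactants
    is produced only by ``source`` and consumed only by itself; the
    qualifying reactions jointly drain the source's products, so deleting
    any one of them silences the source and thereby all the others.
    """
    graph = graph or build_and_or_graph(net)
    dependent = []
    for rid in frontier:
        if rid == source:
            continue
        reactants = [m for m in graph.reactants(rid) if graph.is_connector(m)]
        if not reactants:
            continue
        if all(
            graph.effective_producers(m) == {source} and graph.effective_consumers(m) == {rid}
            for m in reactants
        ):
            dependent.append(rid)
    return frozenset(dependent)


def group_reactions(
    net: MetabolicNetwork,
    depths: DepthMap,
    graph: AndOrGraph | None = None,
) -> list[ReactionGroup]:
    """Partition all reactions into dependency groups.

    Worklist of reactions sorted by (depth, input order); unreachable
    reactions sort last and end up in singleton groups (they are classified
    away later). Each iteration seeds a group with the first worklist entry
    and scans successive depth layers, within each layer repeating the
    linear/flux dependency tests until a fixpoint so that same-layer chains
    (e.g. a reaction and its exclusive consumer landing on one layer) are
    picked up; the scan stops at the first layer that adds nothing or past
    the network's maximum depth.
    """
    graph = graph or build_and_or_graph(net)
    order = {r.id: i for i, r in enumerate(net.reactions)}

    def depth_of(rid: str) -> int:
        return depths.reaction_depth.get(rid, _UNREACHABLE_DEPTH)

    worklist = sorted(net.reaction_ids, key=lambda r: (depth_of(r), order[r]))
    max_depth = depths.max_depth
    groups: list[ReactionGroup] = []
    ungrouped = set(worklist)

    while worklist:
        seed = worklist[0]
        members: list[str] = [seed]
        member_set = {seed}
        d = depth_of(seed)
        while d <= max_depth:
            d += 1
            layer = [r for r in worklist if depth_of(r) == d and r not in member_set]
            added_any = False
            changed = True
            while changed:
                changed = False
                for rid in layer:
                    if rid in member_set:
                        continue
                    if is_linearly_dependent(rid, members, net, graph):
                        members.append(rid)
                        member_set.add(rid)
                        added_any = changed = True
                for src in list(members):
                    hits = find_flux_dependent(
                        src, [r for r in layer if r not in member_set], net, graph
                    )
                    for rid in sorted(hits, key=order.__getitem__):
                        members.append(rid)
                        member_set.add(rid)
                        added_any = changed = True
            if not added_any:
                break
        groups.append(
            ReactionGroup(id=len(groups) + 1, members=tuple(members), depth=depth_of(seed))
        )
        ungrouped -= member_set
        worklist = [r for r in worklist if r in ungrouped]
    return groups
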