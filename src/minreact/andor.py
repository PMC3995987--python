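"""AND-OR graph view of a metabolic network and BFS depth assignment.

The network is viewed as a bipartite directed graph: metabolite nodes,
reaction arcs. A reaction's reactant set is an AND (all must be available);
a metabolite with several producers or consumers is an OR gate (alternative
routes). Depths count reaction layers outward from the medium: extracellular
metabolites and primary uptake reactions sit at depth 1, a metabolite is one
deeper than its shallowest producer, and a reaction sits at the depth of its
shallowest reactant. This reproduces the canonical hand ordering on the
built-in sample network (r1=1, r3=2, r4=3, r5=4; r2=1, r6=2).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

from .network import MetabolicNetwork, ValidationError

__all__ = ["AndOrGraph", "DepthMap", "build_and_or_graph", "assign_depths", "to_dot"]


@dataclass(frozen=True)
class DepthMap:
    metabolite_depth: dict[str, int]
    reaction_depth: dict[str, int]
    unreachable_metabolites: frozenset[str] = frozenset()
    unreachable_reactions: frozenset[str] = frozenset()

    def reaction(self, rid: str) -> int | None:
        return self.reaction_depth.get(rid)

    @property
    def max_depth(self) -> int:
        return max(self.reaction_depth.values(), default=0)


class AndOrGraph:
    """Producer/consumer adjacency with reversibility-aware 'effective' sets.

    ``producers(m)``/``consumers(m)`` follow nominal direction only;
    ``effective_producers``/``effective_consumers`` additionally count a
    reversible reaction on both sides of each of its metabolites, which is
    the conservative view the dependency-grouping exclusivity tests need
    (a reversible alternative route breaks exclusivity regardless of its
    nominal direction).
    """

    def __init__(self, net: MetabolicNetwork, ignored_metabolites: Iterable[str] = ()):
        self.net = net
        self.ignored = frozenset(ignored_metabolites)
        self._producers: dict[str, list[str]] = {m.id: [] for m in net.metabolites}
        self._consumers: dict[str, list[str]] = {m.id: [] for m in net.metabolites}
        for r in net.reactions:
            for mid in r.reactants:
                self._consumers[mid].append(r.id)
            for mid in r.products:
                self._producers[mid].append(r.id)

    def reactants(self, rid: str) -> tuple[str, ...]:
        return self.net.reaction(rid).reactants

    def products(self, rid: str) -> tuple[str, ...]:
        return self.net.reaction(rid).products

    def producers(self, mid: str) -> tuple[str, ...]:
        return tuple(self._producers[mid])

    def consumers(self, mid: str) -> tuple[str, ...]:
        return tuple(self._consumers[mid])

    def effective_producers(self, mid: str) -> frozenset[str]:
        rev = (r for r in self._consumers[mid] if self.net.reaction(r).reversible)
        return frozenset(self._producers[mid]) | frozenset(rev)

    def effective_consumers(self, mid: str) -> frozenset[str]:
        rev = (r for r in self._producers[mid] if self.net.reaction(r).reversible)
        return frozenset(self._consumers[mid]) | frozenset(rev)

    def is_connector(self, mid: str) -> bool:
        """Whether a metabolite counts for dependency/depth propagation."""
        return mid not in self.ignored and not self.net.metabolite(mid).is_extracellular


def build_and_or_graph(
    net: MetabolicNetwork, ignored_metabolites: Iterable[str] = ()
) -> AndOrGraph:
    """``ignored_metabolites`` lets the caller exclude currency metabolites
    (ATP, NADH, ...) as connectors; default is none."""
    return AndOrGraph(net, ignored_metabolites)


def _bfs_depths(
    net: MetabolicNetwork,
    graph: AndOrGraph,
    met_depth: dict[str, int],
    rxn_depth: dict[str, int],
    allow_reverse: bool,
) -> None:
    """0/1-BFS: metabolite -> consuming reaction costs 0 (the reaction sits
    at its shallowest reactant's layer), reaction -> product costs 1 (a new
    layer). Uptake reactions are pinned to depth 1."""
    queue: deque[tuple[int, str, str]] = deque()
    for mid, d in met_depth.items():
        queue.append((d, "m", mid))
    for rid, d in rxn_depth.items():
        queue.append((d, "r", rid))
    while queue:
        d, kind, node = queue.popleft()
        if kind == "m":
            if met_depth.get(node, 1 << 30) < d:
                continue
            for rid in graph.consumers(node):
                if d < rxn_depth.get(rid, 1 << 30):
                    rxn_depth[rid] = d
                    queue.appendleft((d, "r", rid))
            if allow_reverse:
                for rid in graph.producers(node):
                    if net.reaction(rid).reversible and d < rxn_depth.get(rid, 1 << 30):
                        rxn_depth[rid] = d
                        queue.appendleft((d, "r", rid))
        else:
            if rxn_depth.get(node, 1 << 30) < d:
                continue
            products = graph.products(node)
            if allow_reverse and net.reaction(node).reversible:
                products = products + graph.reactants(node)
            for mid in products:
                if d + 1 < met_depth.get(mid, 1 << 30):
                    met_depth[mid] = d + 1
                    queue.append((d + 1, "m", mid))


def assign_depths(
    net: MetabolicNetwork, graph: AndOrGraph | None = None
) -> DepthMap:
    """Assign BFS depths from the depth-1 frontier (extracellular metabolites
    and uptake reactions).

    Propagation follows nominal reaction direction first; a second pass that
    may traverse reversible reactions backwards rescues elements the forward
    pass could not reach. Anything still unreached is reported as
    unreachable rather than given a depth.
    """
    graph = graph or build_and_or_graph(net)
    met_depth = {m.id: 1 for m in net.metabolites if m.is_extracellular}
    rxn_depth = {r.id: 1 for r in net.reactions if r.is_uptake}
    if not met_depth and not rxn_depth:
        raise ValidationError(
            "no depth-1 frontier: network has no extracellular metabolite or uptake reaction"
        )
    _bfs_depths(net, graph, met_depth, rxn_depth, allow_reverse=False)
    if len(rxn_depth) < net.n_reactions or len(met_depth) < net.n_metabolites:
        _bfs_depths(net, graph, met_depth, rxn_depth, allow_reverse=True)
    return DepthMap(
        metabolite_depth=met_depth,
        reaction_depth=rxn_depth,
        unreachable_metabolites=frozenset(m.id for m in net.metabolites if m.id not in met_depth),
        unreachable_reactions=frozenset(r.id for r in net.reactions if r.id not in rxn_depth),
    )


def to_dot(net: MetabolicNetwork, depths: DepthMap | None = None) -> str:
    """DOT rendering of the AND-OR graph with depth labels (debug aid)."""
    lines = ["digraph andor {", "  rankdir=LR;"]
    for m in net.metabolites:
        d = depths.metabolite_depth.get(m.id) if depths else None
        label = f"{m.id}\\nd={d}" if d is not None else m.id
        shape = "doublecircle" if m.is_extracellular else "ellipse"
        lines.append(f'  "{m.id}" [label="{label}", shape={shape}];')
    for r in net.reactions:
        d = depths.reaction_depth.get(r.id) if depths else None
        label = f"{r.id}\\nd={d}" if d is not None else r.id
        lines.append(f'  "{r.id}" [label="{label}", shape=box];')
        for mid in r.reactants:
            lines.append(f'  "{mid}" -> "{r.id}";')
        for mid in r.products:
            lines.append(f'  "{r.id}" -> "{mid}";')
    lines.append("}")
    return "\n".join(lines)
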