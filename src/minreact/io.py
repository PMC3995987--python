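"""Readers and writers: TSV reaction tables, SBML models, JSON results.

The TSV dialect is a plain-text reaction table (tab-separated, UTF-8, ``#``
comments) with columns::

    reaction_id  equation  reversible(0/1)  lb  ub  flags

The equation grammar is ``2 A + B -> C + 0.5 D`` (``<->`` for reversible
arrows); either side may be empty, which models an exchange with the
environment (e.g. a biomass drain ``P ->``). ``flags`` is a comma list from
{biomass, uptake, extracellular-source}. Metabolite ids ending in ``_ext``
default to extracellular.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .network import (
    DEFAULT_FLUX_BOUND,
    FluxVector,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_network_tsv",
    "write_network_tsv",
    "read_sbml",
    "reduce_network",
    "results_to_dict",
    "write_results_json",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?|\.\d+)\s+)?(\S+)$")


def _parse_side(side: str, sign: int, stoich: dict[str, float], line: int) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ParseError("empty term in equation", line)
        m = _TERM_RE.match(term)
        if m is None:
            raise ParseError(f"cannot parse equation term {term!r}", line)
        coef = float(m.group(1)) if m.group(1) else 1.0
        mid = m.group(2)
        stoich[mid] = stoich.get(mid, 0.0) + sign * coef


def _parse_equation(eq: str, line: int) -> tuple[dict[str, float], bool]:
    for arrow, rev in (("<->", True), ("<=>", True), ("->", False)):
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            stoich: dict[str, float] = {}
            _parse_side(left, -1, stoich, line)
            _parse_side(right, +1, stoich, line)
            stoich = {m: c for m, c in stoich.items() if c != 0.0}
            if not stoich:
                raise ParseError("equation has no net stoichiometry", line)
            return stoich, rev
    raise ParseError(f"no arrow ('->' or '<->') in equation {eq!r}", line)


def read_network_tsv(
    path: str | Path,
    biomass_target: float = 1.0,
    uptake_limits: Mapping[str, float] | None = None,
) -> MetabolicNetwork:
    """Parse a reaction-table TSV into a validated network.

    Metabolite order is first-appearance order across equations; reaction
    order is file order. Both orders are load-bearing downstream (depth ties,
    group seeds, knockout ties all break by input order).
    """
    path = Path(path)
    reactions: list[Reaction] = []
    met_order: list[str] = []
    met_flags: dict[str, bool] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        text = raw.split("#", 1)[0].rstrip()
        if not text.strip():
            continue
        cols = text.split("\t")
        if len(cols) < 3:
            raise ParseError(f"expected >=3 tab-separated columns, got {len(cols)}", lineno)
        rid = cols[0].strip()
        if not rid:
            raise ParseError("empty reaction id", lineno)
        stoich, arrow_rev = _parse_equation(cols[1], lineno)
        try:
            reversible = bool(int(cols[2])) if cols[2].strip() else arrow_rev
        except ValueError as exc:
            raise ParseError(f"reversible flag must be 0/1, got {cols[2]!r}", lineno) from exc
        lb = float(cols[3]) if len(cols) > 3 and cols[3].strip() else None
        ub = float(cols[4]) if len(cols) > 4 and cols[4].strip() else None
        flags = {f.strip() for f in cols[5].split(",")} if len(cols) > 5 and cols[5].strip() else set()
        unknown = flags - {"biomass", "uptake", "extracellular-source"}
        if unknown:
            raise ParseError(f"unknown flags {sorted(unknown)}", lineno)
        for mid, coef in stoich.items():
            if mid not in met_flags:
                met_order.append(mid)
                met_flags[mid] = mid.endswith("_ext")
            if "extracellular-source" in flags and coef < 0:
                met_flags[mid] = True
        try:
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    reversible=reversible,
                    lb=lb,
                    ub=ub,
                    is_uptake="uptake" in flags,
                    is_biomass="biomass" in flags,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from exc
    metabolites = [
        Metabolite(id=m, compartment="e" if met_flags[m] else "c", is_extracellular=met_flags[m])
        for m in met_order
    ]
    return MetabolicNetwork(metabolites, reactions, biomass_target, uptake_limits)


def write_network_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    """Inverse of :func:`read_network_tsv` on the network data model."""
    lines = ["# reaction_id\tequation\treversible\tlb\tub\tflags"]
    for r in net.reactions:
        def fmt_side(ids: Sequence[str]) -> str:
            terms = []
            for mid in ids:
                c = abs(r.stoichiometry[mid])
                terms.append(mid if c == 1 else f"{c:g} {mid}")
            return " + ".join(terms)

        arrow = "<->" if r.reversible else "->"
        eq = f"{fmt_side(r.reactants)} {arrow} {fmt_side(r.products)}".strip()
        flags = []
        if r.is_biomass:
            flags.append("biomass")
        if r.is_uptake:
            flags.append("uptake")
        for mid in r.reactants:
            if net.metabolite(mid).is_extracellular and not mid.endswith("_ext"):
                flags.append("extracellular-source")
                break
        lines.append(
            "\t".join([r.id, eq, str(int(r.reversible)), f"{r.lb:g}", f"{r.ub:g}", ",".join(flags)])
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_sbml(
    path: str | Path,
    biomass_id: str,
    uptake_limits: Mapping[str, float] | None = None,
    biomass_target: float = 1.0,
) -> MetabolicNetwork:
    """Load an SBML Level 2/3 model.

    Boundary-condition species map to extracellular metabolites. Reactions
    named in ``uptake_limits`` are marked as uptakes with the given maximum
    rate; fbc flux bounds are honoured when present, otherwise the
    reversibility flag with default bounds.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors() > 0 and any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR for i in range(doc.getNumErrors())
    ):
        raise ParseError(f"unparseable SBML file {path}")
    model = doc.getModel()

    metabolites = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        comp = sp.getCompartment() or "c"
        ext = bool(sp.getBoundaryCondition()) or comp.lower() in ("e", "ext", "extracellular")
        metabolites.append(
            Metabolite(id=sp.getId(), name=sp.getName() or "", compartment=comp, is_extracellular=ext)
        )

    fbc = model.getPlugin("fbc")
    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    uptake_limits = dict(uptake_limits or {})
    reactions = []
    for j in range(model.getNumReactions()):
        rxn = model.getReaction(j)
        stoich: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (ref.getStoichiometry() or 1.0)
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (ref.getStoichiometry() or 1.0)
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich:
            continue
        reversible = rxn.getReversible()
        lb = ub = None
        rfbc = rxn.getPlugin("fbc")
        if rfbc is not None and fbc is not None:
            if rfbc.getLowerFluxBound():
                lb = params.get(rfbc.getLowerFluxBound())
            if rfbc.getUpperFluxBound():
                ub = params.get(rfbc.getUpperFluxBound())
        if lb is not None:
            lb = max(lb, -DEFAULT_FLUX_BOUND)
            reversible = reversible or lb < 0
            if not reversible:
                lb = max(lb, 0.0)
        if ub is not None:
            ub = min(ub, DEFAULT_FLUX_BOUND)
        reactions.append(
            Reaction(
                id=rxn.getId(),
                stoichiometry=stoich,
                reversible=reversible,
                lb=lb,
                ub=ub,
                is_uptake=rxn.getId() in uptake_limits,
                is_biomass=rxn.getId() == biomass_id,
            )
        )
    if not any(r.is_biomass for r in reactions):
        raise ValidationError(f"SBML model has no reaction with id {biomass_id!r}")
    return MetabolicNetwork(metabolites, reactions, biomass_target, uptake_limits)


def _reaction_metabolite_graph(net: MetabolicNetwork) -> nx.Graph:
    """Undirected bipartite graph; extracellular metabolites do not connect."""
    g = nx.Graph()
    for r in net.reactions:
        g.add_node(("r", r.id))
        for mid in r.stoichiometry:
            if not net.metabolite(mid).is_extracellular:
                g.add_edge(("r", r.id), ("m", mid))
    return g


def reduce_network(
    net: MetabolicNetwork,
    seed_reactions: Iterable[str],
    cofactor_pairs: Sequence[tuple[str, str]] = (),
) -> MetabolicNetwork:
    """Restrict to reactions connected (via shared internal metabolites,
    ignoring direction) to the seed set, dropping cofactor-swap duplicates.

    ``cofactor_pairs`` lists equivalent metabolite pairs, e.g.
    ``[("nadh", "nadph"), ("nad", "nadp")]``; among reactions whose
    stoichiometries become identical after merging each pair, only the first
    (or the biomass/seed member) is kept.
    """
    seeds = list(seed_reactions)
    if not seeds:
        raise ValueError("seed_reactions must be non-empty")
    for rid in seeds:
        if not net.has_reaction(rid):
            raise ValueError(f"seed reaction {rid!r} not in network")

    g = _reaction_metabolite_graph(net)
    keep: set[str] = set()
    for rid in seeds:
        keep |= {n[1] for n in nx.node_connected_component(g, ("r", rid)) if n[0] == "r"}

    if cofactor_pairs:
        canon = {}
        for a, b in cofactor_pairs:
            canon[b] = canon.get(a, a)
        seen: dict[tuple, str] = {}
        protected = set(seeds) | {net.biomass_reaction.id}
        for r in net.reactions:
            if r.id not in keep:
                continue
            merged: dict[str, float] = {}
            for mid, c in r.stoichiometry.items():
                key = canon.get(mid, mid)
                merged[key] = merged.get(key, 0.0) + c
            sig = (frozenset(merged.items()), r.reversible)
            if sig in seen:
                if r.id in protected:  # keep the protected copy instead
                    keep.discard(seen[sig])
                    seen[sig] = r.id
                else:
                    keep.discard(r.id)
            else:
                seen[sig] = r.id

    if net.biomass_reaction.id not in keep:
        raise ValidationError("reduction disconnects the biomass reaction")
    sub = net.subnetwork(keep)
    return MetabolicNetwork(
        sub.metabolites,
        sub.reactions,
        biomass_target=net.biomass_target,
        uptake_limits={r: v for r, v in net.uptake_limits.items() if sub.has_reaction(r)},
    )


# -- JSON results -----------------------------------------------------------

def results_to_dict(
    net: MetabolicNetwork,
    result,
    groups=None,
    classification=None,
    knockout_plans=(),
) -> dict:
    """Assemble the result JSON document:
    {network_summary, groups, classification, minimal_sets, knockout_plans,
    iteration_log}."""
    doc: dict = {
        "network_summary": {
            "n_metabolites": net.n_metabolites,
            "n_reactions": net.n_reactions,
            "biomass_reaction": net.biomass_reaction.id,
            "biomass_target": net.biomass_target,
            "uptake_reactions": [r.id for r in net.uptake_reactions],
        },
        "groups": [
            {"id": g.id, "norm": g.norm, "depth": g.depth, "members": list(g.members)}
            for g in (groups or [])
        ],
        "classification": None,
        "minimal_sets": [
            {
                "reactions": sorted(s.reactions),
                "groups": sorted(s.groups),
                "cardinality": s.cardinality,
                "flux": {r: v for r, v in s.flux.values.items() if abs(v) > 1e-9},
            }
            for s in result.minimal_sets
        ],
        "knockout_plans": [
            {
                "minimal_set_id": p.minimal_set_id,
                "knockouts": list(p.knockouts),
                "covered": {k: sorted(v) for k, v in p.covered.items()},
            }
            for p in knockout_plans
        ],
        "iteration_log": list(result.iterations),
        "optimal_cardinality": result.optimal_cardinality,
        "terminated_by": result.terminated_by,
    }
    if classification is not None:
        doc["classification"] = {
            "essential": sorted(classification.essential),
            "extraneous": sorted(classification.extraneous),
            "indeterminate": sorted(classification.indeterminate),
            "forced_essential_overrides": sorted(classification.forced_essential_overrides),
        }
    return doc


def write_results_json(path: str | Path, doc: dict) -> None:
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
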