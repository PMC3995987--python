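"""Phase 2: recursive MILP enumeration of every minimal reaction set.

The MILP attaches one binary y_l to each *indeterminate* group l (norm w_l)
and solves

    minimize   sum_l w_l * y_l
    subject to S.v = 0
               lb_j * y_l <= v_j <= ub_j * y_l   for j in group l (IRG)
               lb_j <= v_j <= ub_j               for essential members
               v_j = 0                           for extraneous members
               v_biomass >= target

Essential groups are permanently active and extraneous ones permanently
off, so only the substitutable core is searched. After each verified
optimum over groups NZ an integer cut

    sum_{l in NZ} y_l <= |NZ| - 1

forces at least one active group out, driving the solver to a different
optimum in the next recursion; the loop stops at the first strictly
sub-optimal objective or infeasibility, at which point every optimum has
been seen. Single-group substitutability (OR-gate groups of equal norm with
identical external metabolite signatures) generates additional candidate
optima from each MILP solution without a MILP solve; candidates are kept
only when a verification LP still reaches the biomass target, and each
accepted candidate is cut as well.

The monolithic variant (one binary per reaction, no grouping/Phase 1/
substitution) is the classical formulation, retained as a validation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .andor import AndOrGraph, assign_depths, build_and_or_graph
from .grouping import ReactionGroup, group_reactions
from .network import FluxVector, MetabolicNetwork
from .phase1 import (
    GroupClassification,
    InfeasibleProblemError,
    TARGET_TOL,
    classify_groups,
    max_biomass_lp,
)

__all__ = [
    "MinimalReactionSet",
    "EnumerationResult",
    "Phase2Model",
    "build_phase2_milp",
    "add_integer_cut",
    "find_substitutable_groups",
    "generate_and_verify_candidates",
    "enumerate_minimal_sets",
    "solve_monolithic",
]

_INT_TOL = 1e-6


@dataclass(frozen=True)
class MinimalReactionSet:
    """One minimum-cardinality reaction subset sustaining the target, with a
    verifying steady-state flux vector."""

    reactions: frozenset[str]
    groups: frozenset[int]
    flux: FluxVector
    cardinality: int

    def __post_init__(self):
        if self.cardinality != len(self.reactions):
            raise ValueError("cardinality must equal |reactions|")


@dataclass
class EnumerationResult:
    minimal_sets: list[MinimalReactionSet]
    optimal_cardinality: int
    iterations: list[dict]
    terminated_by: str  # "suboptimal_solution" | "infeasible"

    @property
    def solution_supports(self) -> set[frozenset[str]]:
        return {s.reactions for s in self.minimal_sets}


class Phase2Model:
    """Incremental MILP over group binaries, re-solved after each cut.

    Variables are the M fluxes followed by one binary per optimizable
    (indeterminate) group. Cuts accumulate as extra constraint rows.
    """

    def __init__(
        self,
        net: MetabolicNetwork,
        groups: Sequence[ReactionGroup],
        classification: GroupClassification,
        biomass_target: float | None = None,
    ):
        self.net = net
        self.groups = {g.id: g for g in groups}
        self.classification = classification
        self.target = net.biomass_target if biomass_target is None else float(biomass_target)
        self.binary_group_ids: list[int] = sorted(classification.indeterminate)
        self._ycol = {gid: net.n_reactions + k for k, gid in enumerate(self.binary_group_ids)}
        self.cuts: list[frozenset[int]] = []
        self._build()

    @property
    def n_binaries(self) -> int:
        return len(self.binary_group_ids)

    def _build(self) -> None:
        net, M = self.net, self.net.n_reactions
        nvar = M + self.n_binaries
        S = net.stoichiometric_matrix(internal_only=True)
        rows_eq = np.hstack([S, np.zeros((S.shape[0], self.n_binaries))]) if S.size else np.zeros((0, nvar))
        self._eq = LinearConstraint(rows_eq, 0.0, 0.0) if rows_eq.size else None

        lb = np.zeros(nvar)
        ub = np.ones(nvar)
        extraneous_members = {
            r for gid in self.classification.extraneous for r in self.groups[gid].members
        }
        binary_member: dict[str, int] = {
            r: gid for gid in self.binary_group_ids for r in self.groups[gid].members
        }
        ineq_rows, ineq_ub = [], []
        for j, rxn in enumerate(net.reactions):
            if rxn.id in extraneous_members:
                lb[j] = ub[j] = 0.0
            elif rxn.id in binary_member:
                # v_j - ub_j*y <= 0  and  lb_j*y - v_j <= 0
                lb[j], ub[j] = min(rxn.lb, 0.0), max(rxn.ub, 0.0)
                k = self._ycol[binary_member[rxn.id]]
                row = np.zeros(nvar); row[j] = 1.0; row[k] = -rxn.ub
                ineq_rows.append(row); ineq_ub.append(0.0)
                row = np.zeros(nvar); row[j] = -1.0; row[k] = rxn.lb
                ineq_rows.append(row); ineq_ub.append(0.0)
            else:  # essential member: plain bounds
                lb[j], ub[j] = rxn.lb, rxn.ub
        brow = np.zeros(nvar)
        brow[net.reaction_position(net.biomass_reaction.id)] = -1.0
        ineq_rows.append(brow); ineq_ub.append(-self.target)
        self._ineq = LinearConstraint(np.array(ineq_rows), -np.inf, np.array(ineq_ub))
        self._bounds = Bounds(lb, ub)
        self._integrality = np.concatenate([np.zeros(M), np.ones(self.n_binaries)])
        c = np.zeros(nvar)
        for gid in self.binary_group_ids:
            c[self._ycol[gid]] = self.groups[gid].norm
        self._c = c

    def add_integer_cut(self, solution_groups: Iterable[int]) -> "Phase2Model":
        """Exclude one previously found active-group pattern:
        sum_{l in NZ} y_l <= |NZ| - 1."""
        nz = frozenset(solution_groups)
        if not nz:
            raise ValueError("integer cut on empty group set")
        unknown = nz - set(self.binary_group_ids)
        if unknown:
            raise ValueError(f"cut references non-binary groups {sorted(unknown)}")
        self.cuts.append(nz)
        return self

    def solve(self) -> tuple[float, dict[int, bool], FluxVector] | None:
        """One MILP solve; returns (objective, active map, flux) or None when
        infeasible (all optima cut or target unreachable)."""
        constraints = [c for c in (self._eq, self._ineq) if c is not None]
        if self.cuts:
            rows = np.zeros((len(self.cuts), len(self._c)))
            ubs = np.zeros(len(self.cuts))
            for i, nz in enumerate(self.cuts):
                for gid in nz:
                    rows[i, self._ycol[gid]] = 1.0
                ubs[i] = len(nz) - 1
            constraints.append(LinearConstraint(rows, -np.inf, ubs))
        res = milp(
            c=self._c,
            constraints=constraints,
            integrality=self._integrality,
            bounds=self._bounds,
        )
        if res.status == 2:  # infeasible
            return None
        if not res.success:
            raise RuntimeError(f"MILP solver failure: {res.message}")
        x = res.x
        active = {
            gid: x[self._ycol[gid]] > 0.5 for gid in self.binary_group_ids
        }
        flux = FluxVector(
            {r.id: float(x[j]) for j, r in enumerate(self.net.reactions)}
        )
        return float(res.fun), active, flux


def build_phase2_milp(
    net: MetabolicNetwork,
    classification: GroupClassification,
    groups: Sequence[ReactionGroup],
    biomass_target: float | None = None,
) -> Phase2Model:
    """Construct the group-binary MILP (one y per indeterminate group)."""
    return Phase2Model(net, groups, classification, biomass_target)


def add_integer_cut(model: Phase2Model, solution_groups: Iterable[int]) -> Phase2Model:
    return model.add_integer_cut(solution_groups)


def _group_signature(g: ReactionGroup, graph: AndOrGraph) -> tuple:
    """External metabolite signature: inputs consumed from outside the group
    and outputs produced for outside, ignoring intra-group intermediates."""
    consumed: set[str] = set()
    produced: set[str] = set()
    for rid in g.members:
        consumed.update(graph.reactants(rid))
        produced.update(graph.products(rid))
    internal = consumed & produced
    return (g.norm, frozenset(consumed - internal), frozenset(produced - internal))


def find_substitutable_groups(
    net: MetabolicNetwork,
    groups: Sequence[ReactionGroup],
    graph: AndOrGraph | None = None,
) -> dict[int, frozenset[int]]:
    """Symmetric map pairing groups of equal norm with identical external
    consume/produce metabolite sets — the OR-gate fans of the AND-OR graph."""
    graph = graph or build_and_or_graph(net)
    by_sig: dict[tuple, list[int]] = {}
    for g in groups:
        by_sig.setdefault(_group_signature(g, graph), []).append(g.id)
    out: dict[int, frozenset[int]] = {}
    for ids in by_sig.values():
        if len(ids) > 1:
            for gid in ids:
                out[gid] = frozenset(ids) - {gid}
    return out


def _verify_candidate(
    net: MetabolicNetwork, candidate_reactions: frozenset[str], target: float
) -> FluxVector | None:
    """LP check: can the candidate subset alone reach the biomass target?"""
    inactive = [r for r in net.reaction_ids if r not in candidate_reactions]
    try:
        opt, flux = max_biomass_lp(net, inactive=inactive)
    except InfeasibleProblemError:
        return None
    return flux if opt >= target - TARGET_TOL else None


def generate_and_verify_candidates(
    solution: MinimalReactionSet,
    substitution_map: Mapping[int, frozenset[int]],
    groups: Sequence[ReactionGroup],
    net: MetabolicNetwork,
    biomass_target: float | None = None,
    known: Iterable[frozenset[str]] = (),
) -> list[MinimalReactionSet]:
    """Single-group substitution on one verified optimum.

    Each active group with substitutes is swapped for each substitute (one
    swap per candidate); a candidate survives only if the max-biomass LP
    restricted to its reactions still reaches the target, in which case the
    verifying flux vector is attached. Known/duplicate supports are dropped.
    """
    target = net.biomass_target if biomass_target is None else float(biomass_target)
    by_id = {g.id: g for g in groups}
    known_set = set(known)
    out: list[MinimalReactionSet] = []
    for gid in sorted(solution.groups):
        for sub in sorted(substitution_map.get(gid, ())):
            if sub in solution.groups:
                continue
            new_groups = (solution.groups - {gid}) | {sub}
            new_reactions = (
                solution.reactions - frozenset(by_id[gid].members)
            ) | frozenset(by_id[sub].members)
            if new_reactions in known_set:
                continue
            flux = _verify_candidate(net, new_reactions, target)
            if flux is None:
                continue
            known_set.add(new_reactions)
            out.append(
                MinimalReactionSet(
                    reactions=new_reactions,
                    groups=frozenset(new_groups),
                    flux=flux,
                    cardinality=len(new_reactions),
                )
            )
    return out


def _clean_flux(flux: FluxVector, active_reactions: frozenset[str]) -> FluxVector:
    return FluxVector(
        {r: (v if r in active_reactions else 0.0) for r, v in flux.values.items()}
    )


def _enumerate(
    net: MetabolicNetwork,
    groups: Sequence[ReactionGroup],
    classification: GroupClassification,
    graph: AndOrGraph,
    target: float,
    use_substitution: bool,
    max_solutions: int | None,
) -> EnumerationResult:
    model = Phase2Model(net, groups, classification, target)
    by_id = {g.id: g for g in groups}
    essential_reactions = frozenset(
        r for gid in classification.essential for r in by_id[gid].members
    )
    substitution_map = (
        find_substitutable_groups(net, groups, graph) if use_substitution else {}
    )
    # restrict substitution to indeterminate groups: essential/extraneous
    # groups are fixed by Phase 1 and must not be swapped.
    substitution_map = {
        gid: subs & classification.indeterminate
        for gid, subs in substitution_map.items()
        if gid in classification.indeterminate
    }

    solutions: list[MinimalReactionSet] = []
    supports: set[frozenset[str]] = set()
    iterations: list[dict] = []
    first_objective: int | None = None
    terminated_by = "infeasible"

    while True:
        solved = model.solve()
        if solved is None:
            terminated_by = "infeasible"
            break
        objective, active, flux = solved
        obj_int = int(round(objective))
        if first_objective is None:
            first_objective = obj_int
        elif obj_int > first_objective:
            terminated_by = "suboptimal_solution"
            iterations.append(
                {
                    "milp_objective": obj_int,
                    "n_candidates_generated": 0,
                    "n_candidates_verified": 0,
                    "cumulative_solutions": len(solutions),
                }
            )
            break
        active_groups = frozenset(gid for gid, on in active.items() if on)
        reactions = essential_reactions | frozenset(
            r for gid in active_groups for r in by_id[gid].members
        )
        sol = MinimalReactionSet(
            reactions=reactions,
            groups=frozenset(classification.essential) | active_groups,
            flux=_clean_flux(flux, reactions),
            cardinality=len(reactions),
        )
        n_generated = n_verified = 0
        if sol.reactions not in supports:
            solutions.append(sol)
            supports.add(sol.reactions)
        if active_groups:
            model.add_integer_cut(active_groups)
        else:
            # essentials alone are optimal: the unique minimum; any
            # alternative must activate groups and cost strictly more.
            terminated_by = "suboptimal_solution"
            iterations.append(
                {
                    "milp_objective": obj_int,
                    "n_candidates_generated": 0,
                    "n_candidates_verified": 0,
                    "cumulative_solutions": len(solutions),
                }
            )
            break
        if use_substitution:
            queue = [sol]
            while queue:
                base = queue.pop(0)
                cands = generate_and_verify_candidates(
                    base, substitution_map, groups, net, target, known=supports
                )
                n_generated += sum(
                    len(substitution_map.get(g, frozenset()) - base.groups)
                    for g in base.groups
                )
                for cand in cands:
                    n_verified += 1
                    solutions.append(cand)
                    supports.add(cand.reactions)
                    model.add_integer_cut(cand.groups & set(model.binary_group_ids))
                    queue.append(cand)
        if max_solutions is not None and len(solutions) >= max_solutions:
            solutions = solutions[:max_solutions]
        iterations.append(
            {
                "milp_objective": obj_int,
                "n_candidates_generated": n_generated,
                "n_candidates_verified": n_verified,
                "cumulative_solutions": len(solutions),
            }
        )
        if max_solutions is not None and len(solutions) >= max_solutions:
            terminated_by = "suboptimal_solution"
            break

    essential_norm = sum(by_id[gid].norm for gid in classification.essential)
    optimal_cardinality = (
        essential_norm + (first_objective or 0)
    )
    return EnumerationResult(
        minimal_sets=solutions,
        optimal_cardinality=optimal_cardinality,
        iterations=iterations,
        terminated_by=terminated_by,
    )


def enumerate_minimal_sets(
    net: MetabolicNetwork,
    biomass_target: float | None = None,
    forced_essential_reactions: Iterable[str] = (),
    ignored_metabolites: Iterable[str] = (),
    use_substitution: bool = True,
    max_solutions: int | None = None,
) -> EnumerationResult:
    """Full grouped pipeline: depth assignment, dependency grouping, Phase-1
    classification, then the recursive MILP with integer cuts and
    substitutability expansion. Returns every minimal reaction set exactly
    once.
    """
    target = net.biomass_target if biomass_target is None else float(biomass_target)
    graph = build_and_or_graph(net, ignored_metabolites)
    depths = assign_depths(net, graph)
    groups = group_reactions(net, depths, graph)
    classification = classify_groups(
        net, groups, target, forced_essential_reactions
    )
    return _enumerate(
        net, groups, classification, graph, target, use_substitution, max_solutions
    )


def solve_monolithic(
    net: MetabolicNetwork,
    biomass_target: float | None = None,
    max_solutions: int | None = None,
) -> EnumerationResult:
    """Classical formulation: one binary per reaction, no grouping, no
    Phase 1, no substitution — the cross-validation mode."""
    target = net.biomass_target if biomass_target is None else float(biomass_target)
    groups = [
        ReactionGroup(id=j + 1, members=(r.id,), depth=1)
        for j, r in enumerate(net.reactions)
    ]
    classification = GroupClassification(
        essential=frozenset(),
        extraneous=frozenset(),
        indeterminate=frozenset(g.id for g in groups),
    )
    opt, _ = max_biomass_lp(net)
    if opt < target - TARGET_TOL:
        raise InfeasibleProblemError(
            f"network cannot reach biomass target {target} (max {opt:.6g})"
        )
    graph = build_and_or_graph(net)
    return _enumerate(
        net, groups, classification, graph, target,
        use_substitution=False, max_solutions=max_solutions,
    )
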