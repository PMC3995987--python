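"""Built-in networks: the 11-reaction worked example, a seeded random
network generator, and a brute-force enumeration oracle.

The random generator and the oracle make the whole pipeline testable
without any external genome-scale model: generated networks are layered
chains with optional parallel (substitutable) reactions, bypasses and
dead ends, and the oracle enumerates minimum-cardinality feasible subsets
by exhaustive LP search — sharing only the LP feasibility primitive with
the main pipeline (no grouping, no MILP, no cuts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .enumerator import MinimalReactionSet
from .network import FluxVector, MetabolicNetwork, Metabolite, Reaction
from .phase1 import InfeasibleProblemError, TARGET_TOL, max_biomass_lp

__all__ = [
    "sample_network",
    "RandomNetworkSpec",
    "random_network",
    "brute_force_minimal_sets",
]

#: Exhaustive-search guard: networks above this size are refused.
BRUTE_FORCE_MAX_REACTIONS = 20
#: Guard on the number of subsets the oracle will LP-test.
BRUTE_FORCE_MAX_SUBSETS = 500_000


def sample_network() -> MetabolicNetwork:
    """The canonical 11-reaction worked example.

    Two nutrients enter (uptakes r1, r2); a four-step chain r1,r3,r4,r5 and
    a two-step chain r2,r6 converge on r9, whose second substrate G is made
    from D by either of the parallel reactions r7/r8 (the OR gate that
    creates two minimal sets); r10 and r11 receive their substrates
    exclusively from r9's two products and drain them, r11 being the
    biomass reaction. All coefficients are 1, uptake bounds 10, biomass
    target 1 — the dependency structure is coefficient-independent for this
    topology.
    """
    met_order = ["A_ext", "A", "B_ext", "B", "C", "E", "F", "D", "G", "H", "I"]
    mets = [
        Metabolite(m, compartment="e" if m.endswith("_ext") else "c",
                   is_extracellular=m.endswith("_ext"))
        for m in met_order
    ]
    rxn = [
        Reaction("r1", {"A_ext": -1, "A": 1}, is_uptake=True, ub=10),
        Reaction("r2", {"B_ext": -1, "B": 1}, is_uptake=True, ub=10),
        Reaction("r3", {"A": -1, "C": 1}),
        Reaction("r4", {"C": -1, "E": 1}),
        Reaction("r5", {"E": -1, "F": 1}),
        Reaction("r6", {"B": -1, "D": 1}),
        Reaction("r7", {"D": -1, "G": 1}),
        Reaction("r8", {"D": -1, "G": 1}),
        Reaction("r9", {"F": -1, "G": -1, "H": 1, "I": 1}),
        Reaction("r10", {"H": -1}),
        Reaction("r11", {"I": -1}, is_biomass=True),
    ]
    return MetabolicNetwork(mets, rxn, biomass_target=1.0)


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Parameters of a generated layered network.

    ``n_metabolites`` counts backbone metabolites (extracellular plus chain
    intermediates); dead-end products added as extras come on top.
    ``branch_probability`` picks, per extra reaction, a duplicate of an
    existing internal reaction (an OR gate / substitutable pair) rather
    than a bypass or dead end; ``reversible_fraction`` is the chance each
    non-uptake reaction is reversible.
    """

    n_metabolites: int = 8
    n_reactions: int = 10
    n_uptakes: int = 1
    branch_probability: float = 0.5
    reversible_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_uptakes < 1:
            raise ValueError("need at least one uptake")
        if not (0 <= self.branch_probability <= 1 and 0 <= self.reversible_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_metabolites < 2 * self.n_uptakes:
            raise ValueError("need an external and an internal metabolite per uptake")


def _build_random(spec: RandomNetworkSpec, rng: np.random.Generator) -> MetabolicNetwork:
    n_internal = spec.n_metabolites - spec.n_uptakes
    base = spec.n_uptakes  # chain heads
    lengths = [n_internal // spec.n_uptakes] * spec.n_uptakes
    for i in range(n_internal - sum(lengths)):
        lengths[i] += 1

    mets: list[Metabolite] = []
    reactions: list[Reaction] = []
    chain_mets: list[list[str]] = []
    for u in range(spec.n_uptakes):
        ext = f"X{u + 1}_ext"
        mets.append(Metabolite(ext, compartment="e", is_extracellular=True))
        chain = [f"m{u + 1}_{i + 1}" for i in range(lengths[u])]
        mets.extend(Metabolite(m) for m in chain)
        reactions.append(
            Reaction(f"u{u + 1}", {ext: -1, chain[0]: 1}, is_uptake=True, ub=10)
        )
        for i in range(len(chain) - 1):
            reactions.append(
                Reaction(f"c{u + 1}_{i + 1}", {chain[i]: -1, chain[i + 1]: 1})
            )
        chain_mets.append(chain)
    reactions.append(
        Reaction(
            "biomass",
            {chain[-1]: -1 for chain in chain_mets},
            is_biomass=True,
        )
    )

    n_base = len(reactions)
    n_extra = spec.n_reactions - n_base
    if n_extra < 0:
        raise ValueError(
            f"n_reactions={spec.n_reactions} below the {n_base} backbone reactions"
        )
    internal_ids = [r.id for r in reactions if not (r.is_uptake or r.is_biomass)]
    dead_ends = 0
    for k in range(n_extra):
        roll = rng.random()
        if internal_ids and roll < spec.branch_probability:
            # duplicate an internal reaction -> substitutable OR pair
            src = reactions[[r.id for r in reactions].index(rng.choice(internal_ids))]
            reactions.append(Reaction(f"dup{k + 1}", dict(src.stoichiometry)))
        elif roll < (1 + spec.branch_probability) / 2 and any(len(c) > 2 for c in chain_mets):
            # bypass within one chain: m_i -> m_j, j > i+1
            chain = chain_mets[int(rng.integers(len(chain_mets)))]
            if len(chain) > 2:
                i = int(rng.integers(0, len(chain) - 2))
                j = int(rng.integers(i + 2, len(chain)))
                reactions.append(
                    Reaction(f"bp{k + 1}", {chain[i]: -1, chain[j]: 1})
                )
            else:
                dead_ends += 1
                mets.append(Metabolite(f"dead{dead_ends}"))
                reactions.append(
                    Reaction(f"de{dead_ends}", {chain[0]: -1, f"dead{dead_ends}": 1})
                )
        else:
            # dead end: product nothing consumes -> extraneous reaction
            dead_ends += 1
            src_chain = chain_mets[int(rng.integers(len(chain_mets)))]
            src = src_chain[int(rng.integers(len(src_chain)))]
            mets.append(Metabolite(f"dead{dead_ends}"))
            reactions.append(
                Reaction(f"de{dead_ends}", {src: -1, f"dead{dead_ends}": 1})
            )
    final = []
    for r in reactions:
        if not r.is_uptake and not r.is_biomass and rng.random() < spec.reversible_fraction:
            final.append(
                Reaction(r.id, dict(r.stoichiometry), reversible=True, lb=-10.0, ub=r.ub)
            )
        else:
            final.append(r)
    return MetabolicNetwork(mets, final, biomass_target=1.0)


def random_network(spec: RandomNetworkSpec, max_attempts: int = 20) -> MetabolicNetwork:
    """Seeded, reproducible layered network with the biomass target
    guaranteed reachable (the generator redraws until the max-biomass LP
    clears the target, up to ``max_attempts``)."""
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_attempts):
        net = _build_random(spec, rng)
        try:
            opt, _ = max_biomass_lp(net)
        except InfeasibleProblemError:
            continue
        if opt >= net.biomass_target - TARGET_TOL:
            return net
    raise RuntimeError(
        f"could not generate a feasible network for {spec} in {max_attempts} attempts"
    )


def brute_force_minimal_sets(
    net: MetabolicNetwork, biomass_target: float | None = None
) -> list[MinimalReactionSet]:
    """Independent enumeration oracle: exhaustive cardinality-ascending
    subset search with an LP feasibility test per subset.

    Pruning stays purely LP-based so the oracle remains independent of the
    grouping/MILP pipeline: reactions whose single deletion already defeats
    the target must be in every feasible subset, so only subsets containing
    all of them are enumerated. Returns all feasible
    subsets at the first cardinality admitting any (cardinality-first
    search makes minimality automatic); empty when the target is
    infeasible even with every reaction active.
    """
    target = net.biomass_target if biomass_target is None else float(biomass_target)
    M = net.n_reactions
    if M > BRUTE_FORCE_MAX_REACTIONS:
        raise ValueError(
            f"network has {M} reactions; oracle guard is {BRUTE_FORCE_MAX_REACTIONS}"
        )
    try:
        opt, _ = max_biomass_lp(net)
    except InfeasibleProblemError:
        return []
    if opt < target - TARGET_TOL:
        return []

    def feasible(subset: frozenset[str]) -> FluxVector | None:
        inactive = [r for r in net.reaction_ids if r not in subset]
        try:
            value, flux = max_biomass_lp(net, inactive=inactive)
        except InfeasibleProblemError:
            return None
        return flux if value >= target - TARGET_TOL else None

    required: set[str] = set()
    free: list[str] = []
    for rid in net.reaction_ids:
        try:
            value, _ = max_biomass_lp(net, inactive=[rid])
        except InfeasibleProblemError:
            value = -math.inf
        if value < target - TARGET_TOL:
            required.add(rid)
        else:
            free.append(rid)

    n_subsets = 0
    for k in range(len(free) + 1):
        n_subsets += math.comb(len(free), k)
        if n_subsets > BRUTE_FORCE_MAX_SUBSETS:
            raise ValueError("oracle subset budget exceeded; shrink the network")
        found: list[MinimalReactionSet] = []
        for combo in combinations(free, k):
            subset = frozenset(required) | frozenset(combo)
            flux = feasible(subset)
            if flux is not None:
                found.append(
                    MinimalReactionSet(
                        reactions=subset,
                        groups=frozenset(),
                        flux=FluxVector(
                            {r: (flux.get(r) if r in subset else 0.0) for r in net.reaction_ids}
                        ),
                        cardinality=len(subset),
                    )
                )
        if found:
            return found
    return []
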