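import pytest

from minreact import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    assign_depths,
    build_and_or_graph,
    group_reactions,
    sample_network,
)


def net_from_reactions(reactions, biomass_target=1.0, uptake_limits=None):
    """Build a network from Reaction objects, inferring the metabolite list
    (ids ending in _ext become extracellular), preserving first-appearance
    order."""
    seen = []
    for r in reactions:
        for mid in r.stoichiometry:
            if mid not in seen:
                seen.append(mid)
    mets = [
        Metabolite(m, compartment="e" if m.endswith("_ext") else "c",
                   is_extracellular=m.endswith("_ext"))
        for m in seen
    ]
    return MetabolicNetwork(mets, reactions, biomass_target, uptake_limits)


def linear_chain(k):
    """uptake -> m1 -> ... -> m_{k-1} -> biomass: k reactions, one pathway."""
    assert k >= 2
    rxns = [Reaction("u", {"S_ext": -1, "m1": 1}, is_uptake=True, ub=10)]
    for i in range(1, k - 1):
        rxns.append(Reaction(f"r{i}", {f"m{i}": -1, f"m{i + 1}": 1}))
    rxns.append(Reaction("bio", {f"m{k - 1}": -1}, is_biomass=True))
    return net_from_reactions(rxns)


@pytest.fixture(scope="session")
def sample():
    return sample_network()


@pytest.fixture(scope="session")
def sample_graph(sample):
    return build_and_or_graph(sample)


@pytest.fixture(scope="session")
def sample_depths(sample, sample_graph):
    return assign_depths(sample, sample_graph)


@pytest.fixture(scope="session")
def sample_groups(sample, sample_depths, sample_graph):
    return group_reactions(sample, sample_depths, sample_graph)
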