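"""Phase-2 MILP, integer cuts, substitutability, and full enumeration."""

import pytest

from minreact import (
    GroupClassification,
    InfeasibleProblemError,
    RandomNetworkSpec,
    Reaction,
    assign_depths,
    brute_force_minimal_sets,
    build_and_or_graph,
    build_phase2_milp,
    classify_groups,
    enumerate_minimal_sets,
    find_substitutable_groups,
    generate_and_verify_candidates,
    group_reactions,
    random_network,
    solve_monolithic,
)
from conftest import linear_chain, net_from_reactions


@pytest.fixture(scope="module")
def sample_pipeline(sample, sample_depths, sample_graph, sample_groups):
    cls = classify_groups(sample, sample_groups)
    return sample, sample_groups, cls, sample_graph


class TestPhase2Milp:
    def test_one_binary_per_indeterminate_group(self, sample_pipeline):
        net, groups, cls, _ = sample_pipeline
        model = build_phase2_milp(net, cls, groups)
        assert model.n_binaries == len(cls.indeterminate) == 2

    def test_optimum_selects_one_or_gate_branch(self, sample_pipeline):
        net, groups, cls, _ = sample_pipeline
        model = build_phase2_milp(net, cls, groups)
        objective, active, flux = model.solve()
        assert objective == pytest.approx(1.0)
        assert sum(active.values()) == 1
        assert flux[net.biomass_reaction.id] >= net.biomass_target - 1e-6

    def test_empty_indeterminate_gives_trivial_model(self):
        net = linear_chain(4)
        groups = group_reactions(net, assign_depths(net))
        cls = classify_groups(net, groups)
        assert not cls.indeterminate
        model = build_phase2_milp(net, cls, groups)
        objective, active, _ = model.solve()
        assert objective == pytest.approx(0.0)
        assert not any(active.values())

    def test_grouped_objective_equals_oracle_cardinality_minus_essentials(self):
        for seed in range(6):
            spec = RandomNetworkSpec(
                n_metabolites=8, n_reactions=12, n_uptakes=2,
                branch_probability=0.7, reversible_fraction=0.0, seed=seed,
            )
            net = random_network(spec)
            groups = group_reactions(net, assign_depths(net))
            cls = classify_groups(net, groups)
            by_id = {g.id: g for g in groups}
            essential_norm = sum(by_id[g].norm for g in cls.essential)
            objective, _, _ = build_phase2_milp(net, cls, groups).solve()
            oracle = brute_force_minimal_sets(net)
            assert round(objective) == oracle[0].cardinality - essential_norm


class TestIntegerCuts:
    def test_cut_changes_active_set(self, sample_pipeline):
        net, groups, cls, _ = sample_pipeline
        model = build_phase2_milp(net, cls, groups)
        _, active1, _ = model.solve()
        first = frozenset(g for g, on in active1.items() if on)
        model.add_integer_cut(first)
        _, active2, _ = model.solve()
        assert frozenset(g for g, on in active2.items() if on) != first

    def test_cutting_all_optima_exhausts_model(self, sample_pipeline):
        """After both OR-gate branches are cut the model is infeasible (or
        strictly worse) — the recursion's termination certificate."""
        net, groups, cls, _ = sample_pipeline
        model = build_phase2_milp(net, cls, groups)
        objective0 = None
        for _ in range(2):
            solved = model.solve()
            assert solved is not None
            objective, active, _ = solved
            objective0 = objective0 if objective0 is not None else objective
            model.add_integer_cut(frozenset(g for g, on in active.items() if on))
        final = model.solve()
        assert final is None or final[0] > objective0 + 0.5

    def test_cuts_are_cumulative_and_exact(self):
        """On a 3-parallel-branch toy, k cuts exclude exactly the k cut
        patterns; enumeration visits each branch once."""
        net = net_from_reactions([
            Reaction("u", {"S_ext": -1, "A": 1}, is_uptake=True, ub=10),
            Reaction("p1", {"A": -1, "B": 1}),
            Reaction("p2", {"A": -1, "B": 1}),
            Reaction("p3", {"A": -1, "B": 1}),
            Reaction("bio", {"B": -1}, is_biomass=True),
        ])
        groups = group_reactions(net, assign_depths(net))
        cls = classify_groups(net, groups)
        model = build_phase2_milp(net, cls, groups)
        seen = []
        while True:
            solved = model.solve()
            if solved is None:
                break
            _, active, _ = solved
            nz = frozenset(g for g, on in active.items() if on)
            assert nz not in seen, "cut failed to exclude a previous optimum"
            seen.append(nz)
            model.add_integer_cut(nz)
        assert len(seen) == 3

    def test_empty_cut_rejected(self, sample_pipeline):
        net, groups, cls, _ = sample_pipeline
        model = build_phase2_milp(net, cls, groups)
        with pytest.raises(ValueError):
            model.add_integer_cut(frozenset())


class TestSubstitutability:
    def test_sample_or_gate_pair(self, sample_pipeline):
        net, groups, _, graph = sample_pipeline
        sub = find_substitutable_groups(net, groups, graph)
        by_members = {g.members: g.id for g in groups}
        g7, g8 = by_members[("r7",)], by_members[("r8",)]
        assert sub == {g7: frozenset({g8}), g8: frozenset({g7})}

    def test_no_parallel_routes_empty_map(self):
        net = linear_chain(5)
        groups = group_reactions(net, assign_depths(net))
        assert find_substitutable_groups(net, groups) == {}

    def test_three_isofunctional_reactions(self):
        net = net_from_reactions([
            Reaction("u", {"S_ext": -1, "A": 1}, is_uptake=True, ub=10),
            Reaction("p1", {"A": -1, "B": 1}),
            Reaction("p2", {"A": -1, "B": 1}),
            Reaction("p3", {"A": -1, "B": 1}),
            Reaction("bio", {"B": -1}, is_biomass=True),
        ])
        groups = group_reactions(net, assign_depths(net))
        sub = find_substitutable_groups(net, groups)
        par = [g.id for g in groups if g.members[0].startswith("p")]
        for gid in par:
            assert sub[gid] == frozenset(par) - {gid}

    def test_candidates_generated_and_verified(self, sample_pipeline):
        net, groups, cls, graph = sample_pipeline
        result = enumerate_minimal_sets(net, max_solutions=1)
        sol = result.minimal_sets[0]
        sub = find_substitutable_groups(net, groups, graph)
        cands = generate_and_verify_candidates(sol, sub, groups, net)
        assert len(cands) == 1
        assert cands[0].cardinality == sol.cardinality
        assert cands[0].reactions != sol.reactions

    def test_failing_candidate_excluded(self):
        """Same external signature but an unusably tight bound: the swap is
        generated, fails the verification LP, and is dropped."""
        net = net_from_reactions([
            Reaction("u", {"S_ext": -1, "A": 1}, is_uptake=True, ub=10),
            Reaction("p1", {"A": -1, "B": 1}),
            Reaction("p2", {"A": -1, "B": 1}, ub=0.1),  # too weak for target
            Reaction("bio", {"B": -1}, is_biomass=True),
        ])
        groups = group_reactions(net, assign_depths(net))
        graph = build_and_or_graph(net)
        cls = classify_groups(net, groups)
        result = enumerate_minimal_sets(net)
        assert len(result.minimal_sets) == 1
        assert "p1" in result.minimal_sets[0].reactions
        sub = find_substitutable_groups(net, groups, graph)
        cands = generate_and_verify_candidates(
            result.minimal_sets[0], sub, groups, net
        )
        assert cands == []

    def test_no_substitutable_groups_empty_list(self):
        net = linear_chain(4)
        groups = group_reactions(net, assign_depths(net))
        result = solve_monolithic(net)
        assert generate_and_verify_candidates(
            result.minimal_sets[0], {}, groups, net
        ) == []


class TestEnumeration:
    def test_sample_two_minimal_sets(self, sample):
        result = enumerate_minimal_sets(sample)
        assert result.optimal_cardinality == 10
        supports = result.solution_supports
        assert len(supports) == 2
        union = set.union(*map(set, supports))
        inter = set.intersection(*map(set, supports))
        assert union - inter == {"r7", "r8"}

    def test_matches_brute_force_oracle(self, sample):
        oracle = {s.reactions for s in brute_force_minimal_sets(sample)}
        assert enumerate_minimal_sets(sample).solution_supports == oracle

    def test_monolithic_matches_grouped(self, sample):
        mono = solve_monolithic(sample)
        grouped = enumerate_minimal_sets(sample)
        assert mono.solution_supports == grouped.solution_supports
        assert mono.optimal_cardinality == grouped.optimal_cardinality

    def test_substitution_shortcut_changes_nothing(self, sample):
        with_sub = enumerate_minimal_sets(sample, use_substitution=True)
        without = enumerate_minimal_sets(sample, use_substitution=False)
        assert with_sub.solution_supports == without.solution_supports

    def test_solution_invariants(self, sample, sample_groups):
        cls = classify_groups(sample, sample_groups)
        by_id = {g.id: g for g in sample_groups}
        result = enumerate_minimal_sets(sample)
        for sol in result.minimal_sets:
            assert sol.cardinality == result.optimal_cardinality
            for gid in cls.essential:
                assert set(by_id[gid].members) <= sol.reactions
            assert sample.mass_balance_residual(sol.flux) < 1e-6
            assert sol.flux[sample.biomass_reaction.id] >= sample.biomass_target - 1e-6
            for rid in sample.reaction_ids:
                if rid not in sol.reactions:
                    assert sol.flux[rid] == 0.0

    def test_iteration_log_structure(self, sample):
        result = enumerate_minimal_sets(sample)
        assert result.iterations
        for entry in result.iterations:
            assert {"milp_objective", "n_candidates_generated",
                    "n_candidates_verified", "cumulative_solutions"} <= entry.keys()
        assert result.iterations[-1]["cumulative_solutions"] == len(result.minimal_sets)

    def test_unique_solution_network(self):
        net = linear_chain(5)
        result = enumerate_minimal_sets(net)
        assert len(result.minimal_sets) == 1
        assert result.minimal_sets[0].reactions == frozenset(net.reaction_ids)
        assert solve_monolithic(net).solution_supports == result.solution_supports

    def test_infeasible_target_errors(self, sample):
        with pytest.raises(InfeasibleProblemError):
            enumerate_minimal_sets(sample, biomass_target=100.0)
        with pytest.raises(InfeasibleProblemError):
            solve_monolithic(sample, biomass_target=100.0)

    def test_max_solutions_truncates(self, sample):
        result = enumerate_minimal_sets(sample, max_solutions=1)
        assert len(result.minimal_sets) == 1
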