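# minreact

Enumerate **every minimal reaction set** of a steady-state metabolic
network: the smallest subsets of reactions that, with all other reactions
forced to zero flux, still satisfy mass balance, flux bounds and a minimum
biomass production target. Minimal reaction sets are the computational
blueprint for minimal-metabolism cell designs — and because redundant
pathways create many alternate optima with very different practical
properties (cycles, extreme cofactor-recycling fluxes), finding *all* of
them matters, not just one.

## The method

A network with `N` metabolites and `M` reactions obeys steady-state mass
balance `Σ_j S_ij v_j = 0` with bounds `v_j^min ≤ v_j ≤ v_j^max`. The
monolithic formulation attaches a binary `y_j` to each reaction and solves

```
min Σ_j y_j   s.t.   S v = 0,   v_j^min y_j ≤ v_j ≤ v_j^max y_j,
                     v_biomass ≥ v_target,   y_j ∈ {0,1}
```

which scales poorly. `minreact` shrinks and recursively re-solves this
program using the network's structure:

1. **AND-OR graph + depths.** Metabolites are nodes and reactions arcs;
   co-reactants form AND gates, alternative producers/consumers OR gates.
   Extracellular metabolites and primary uptake reactions sit at depth 1
   and breadth-first search layers everything else outward.
2. **Dependency grouping.** Reactions whose fluxes are structurally forced
   to vanish together (linear pathways; branch points whose products feed
   obligatory sinks) are grouped; one binary per group suffices. The group
   size is its *norm*, the group's weight in the objective.
3. **Phase 1 classification.** Each group is tested against the biomass
   target: deleting it infeasible → *essential* (in every minimal set);
   zero flux range under the target → *extraneous* (in none); the rest are
   *indeterminate* — the substitutable core.
4. **Phase 2 recursive MILP.** A MILP over the indeterminate groups
   (objective `Σ_l w_l y_l`, `w_l` = norm) finds one optimum; an integer
   cut `Σ_{l∈NZ} y_l ≤ |NZ| − 1` excludes it and the solve repeats until
   the objective degrades or the model empties. Between solves,
   *substitutability analysis* swaps an active group for an equal-norm
   OR-gate twin and keeps candidates that pass a biomass-maximization LP —
   extra optima at LP rather than MILP cost.
5. **Knockout plans.** For a chosen minimal set, a greedy lowest-depth
   loop picks the deletions that silence the entire complement.

A brute-force oracle (exhaustive cardinality-ascending subset search with
LP feasibility tests) and a monolithic mode cross-validate the pipeline on
every small network in the test suite.

## Worked example

The built-in 11-reaction network has two uptakes (r1: A_ext, r2: B_ext),
two converging chains, and one OR gate (r7/r8 both convert D to G):

```python
import minreact as mr

net = mr.sample_network()
depths = mr.assign_depths(net)
groups = mr.group_reactions(net, depths)
for g in groups:
    print(f"group {g.id}: norm={g.norm} depth={g.depth} members={', '.join(g.members)}")
cls = mr.classify_groups(net, groups)
print("essential groups:", sorted(cls.essential), "indeterminate:", sorted(cls.indeterminate))
result = mr.enumerate_minimal_sets(net)
print(f"{len(result.minimal_sets)} minimal sets of {result.optimal_cardinality} reactions")
for s in result.minimal_sets:
    print(" ", sorted(s.reactions, key=net.reaction_position))
plan = mr.select_knockouts(net, result.minimal_sets[0], depths, groups)
print("knockouts for set 0:", plan.knockouts)
```

prints

```
group 1: norm=7 depth=1 members=r1, r3, r4, r5, r9, r10, r11
group 2: norm=2 depth=1 members=r2, r6
group 3: norm=1 depth=3 members=r7
group 4: norm=1 depth=3 members=r8
essential groups: [1, 2] indeterminate: [3, 4]
2 minimal sets of 10 reactions
  ['r1', 'r2', 'r3', 'r4', 'r5', 'r6', 'r7', 'r9', 'r10', 'r11']
  ['r1', 'r2', 'r3', 'r4', 'r5', 'r6', 'r8', 'r9', 'r10', 'r11']
knockouts for set 0: ('r8',)
```

Group 1 is the seven-reaction dependency group seeded at r1; the OR-gate
groups {r7} and {r8} are the only indeterminate ones, so the 11-binary
monolithic search collapses to a 2-binary MILP. The two minimal sets
differ only in which parallel reaction carries the D→G conversion, and
realizing either requires a single knockout.

The same pipeline is available from the shell:

```
minreact fixture sample --out net.tsv
minreact enumerate net.tsv --biomass-target 1.0 --out results.json \
    --iteration-log iters.tsv --knockout-plans
minreact knockouts net.tsv results.json --set 0
```

Genome-scale models load from SBML
(`minreact enumerate model.xml --format sbml --biomass-id BIOMASS ...`),
with `minreact.reduce_network` available to restrict a model to the
subnetwork connected to a pathway of interest and to drop cofactor-swap
duplicate reactions before enumeration.

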