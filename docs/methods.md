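# Methods

## Problem statement and model

A metabolic network is a stoichiometric matrix `S` (`N` metabolites × `M`
reactions) under the steady-state assumption `S v = 0`, flux bounds
`v^min ≤ v ≤ v^max`, one designated biomass reaction, and designated
uptake reactions whose upper bounds encode the medium (e.g. a glucose
uptake of 10 mmol/gDW·h is an explicit uptake reaction with `ub = 10`).
Extracellular (boundary) metabolites are tracked but excluded from the
mass-balance rows: they represent an unbounded environment, and balancing
them would force every exchange flux to zero. Uptake and secretion are
therefore ordinary reactions and count toward set cardinalities.

A **minimal reaction set** is a minimum-cardinality subset `R` such that
biomass flux ≥ target is feasible with `v_j = 0` for all `j ∉ R`. Two
facts shape the algorithm. First, at minimum cardinality every member of a
feasible subset carries flux in every witness (otherwise dropping the idle
reaction would give a smaller feasible subset), so minimal sets are
exactly the minimum-cardinality *supports* of feasible flux vectors.
Second, structurally coupled reactions are active or silent together, so
the search can run over coupled groups instead of single reactions.

## Depth assignment

The AND-OR graph view: metabolite nodes, reaction arcs; a reaction's
reactant set is an AND, a metabolite's alternative producers/consumers an
OR. Depths count reaction layers from the medium:

* extracellular metabolites and primary uptake reactions: depth 1;
* a metabolite: 1 + the depth of its shallowest producer;
* a reaction: the depth of its shallowest reactant (equivalently one past
  its predecessor reaction).

This is a 0/1-BFS (metabolite→consumer edges cost 0, reaction→product
edges cost 1), so cycles terminate at first visit and the assignment is
deterministic and order-independent. On the built-in sample network it
yields the canonical hand ordering r1=1, r3=2, r4=3, r5=4 and r2=1, r6=2.
Propagation follows nominal reaction direction first; a second pass may
traverse reversible reactions backwards to rescue otherwise unreachable
elements, keeping depths aligned with nutrient flow where possible.
Elements still unreached are flagged unreachable rather than assigned a
depth. An optional ignore-list excludes currency metabolites (ATP,
NADH, …) as graph connectors; it defaults to empty because the built-in
fixtures carry no currency metabolites, and is a modelling choice the user
must own for genome-scale inputs.

## Dependency grouping

The coupling certificate is a shared internal metabolite `m` with no
alternative route: if `m`'s producers all lie in a reaction set `G` and
its sole consumer is reaction `c`, steady state forces `c` and `G`'s
members to be silent together. Two test forms are exposed:

* **linear dependency** — candidate `c` joins group `G` when at least one
  of its reactants has this exclusive form. One exclusive reactant
  suffices: in the sample network r9 joins the r1-chain because its
  substrate F comes only from r5, even though its other substrate G has
  two producers. The certificate metabolite alone already couples the
  fluxes, so the group stays sound.
* **flux dependency** — several reactions join at once when each receives
  every reactant exclusively from one group member and is its sole
  consumer (r10 and r11 jointly draining r9's two products).

Exclusivity is evaluated on reversibility-aware producer/consumer sets: a
reversible reaction counts on both sides of each of its metabolites, so a
reversible alternative route breaks exclusivity regardless of its written
direction. The asymmetry of cost drives this choice: a too-fine group only
costs solver time, a too-coarse one would corrupt the enumeration. The
all-or-none soundness property is verified in the test suite by LP-probing
every multi-member group on random networks (force one member to zero,
check every other member's flux range collapses to (0, 0)).

Group construction walks a worklist sorted by (depth, input order): seed a
group with the first entry, scan successive depth layers, within a layer
repeat both dependency tests to a fixpoint (so same-layer chains are
collected), stop at the first unproductive layer, remove the members, and
repeat. Ties always break by input order, making the partition
deterministic. Dependents are accepted relative to *any* current member,
not only the most recently added one — the natural reading of a
breadth-first scan, and the fixpoint iteration makes the result
insensitive to within-layer ordering.

## Phase 1: group classification

Functional tests against the biomass target (no subnetwork decomposition;
both tests are LPs on the full network):

* **essential**: maximum biomass with the group inactive falls short of
  the target (tolerance 1e-6 on the comparison);
* **extraneous**: every member's flux range under the biomass floor is
  (0, 0) within 1e-9;
* **indeterminate**: everything else.

Both tests are sound in the direction that matters: a group is only
*fixed* (essential/extraneous) when provably so, and anything unresolved
stays indeterminate and is settled exactly by the Phase-2 MILP — so
classification conservatism can never change the enumerated solution set,
only the number of binaries. A `forced_essential_reactions` list lets the
modeller promote groups (e.g. compartment transport reactions in
genome-scale models); it is never inferred.

## Phase 2: recursive MILP with integer cuts

One binary per indeterminate group; members of group `l` get
`lb_j·y_l ≤ v_j ≤ ub_j·y_l`; essential members keep plain bounds;
extraneous members are fixed at zero; biomass ≥ target. The objective
`Σ w_l y_l` (w = norm) counts selected reactions, so the optimum plus the
essential norm total is the minimal-set cardinality. Because every weight
is positive, an optimal solution never carries an active group at zero
flux, and grouping soundness makes each optimum's active set a genuine
support.

After each verified optimum over active groups `NZ` the unweighted integer
cut `Σ_{l∈NZ} y_l ≤ |NZ| − 1` is added — "at least one active group must
switch off" — restricted to indeterminate groups, since essentials are
permanently active and would make a wider cut vacuous. Recursion stops
when the objective strictly exceeds the first optimum or the model becomes
infeasible; at that point the cut pool covers every optimum, so the
enumeration is complete. Spurious supersets (an optimal support plus an
idle group) always cost strictly more than the optimum and therefore
cannot be emitted as solutions.

**Substitutability shortcut.** Groups of equal norm with identical
external consume/produce metabolite signatures (OR-gate fans) are
interchangeable candidates. After each MILP optimum, each active group is
swapped for each of its substitutes (single-group substitution only; the
swap closure over newly accepted optima is also explored), every candidate
is verified by a biomass-maximization LP with all non-candidate reactions
inactive, survivors are recorded and cut exactly like MILP optima, and
failures are discarded (and not cut — they were never in the feasible
pool). The shortcut is a pure accelerator: the cut-driven recursion finds
any optimum substitution misses, and the test suite checks that disabling
it changes nothing.

The **monolithic mode** (one binary per reaction, no grouping/Phase 1/
substitution) is retained as an independent validation path and must —
and in tests does — return the identical solution set.

## Knockout plans

To realize a minimal set in a strain, the complement is walked in
ascending depth (input order on ties); each chosen knockout removes
itself, its group co-members, and every remaining complement reaction
whose flux range collapses to (0, 0) once the accumulated deletions are
applied — the flux check catches cross-group cascades that pure group
membership misses. The loop ends with the complement exactly covered, so
deleting the plan's reactions leaves precisely the minimal set able to
carry flux.

## Synthetic data and the oracle

The random-network generator emulates the structural features the method
exercises: layered uptake-to-biomass chains (nontrivial groups), duplicate
reactions (OR gates / substitutable pairs, hence multiple optima),
bypasses (alternate path lengths), dead ends (extraneous reactions) and a
configurable reversible fraction, with seeds making every draw
reproducible and a retry loop guaranteeing the biomass target is
reachable. Defaults (8 backbone metabolites, 10 reactions, 1 uptake,
branch probability 0.5, no reversibility, uptake bound 10, target 1)
give networks small enough for exhaustive search yet rich enough to
populate all three Phase-1 classes. Generated networks do not reproduce
genome-scale statistics — no compartments, no cofactor coupling, no
hub metabolites — so passing tests certify algorithmic correctness
(enumeration exactly matches exhaustive search), not biological realism
of any particular model.

The brute-force oracle enumerates subsets cardinality-first, LP-testing
each for target feasibility, and returns all feasible subsets at the first
feasible cardinality; it shares only the LP primitive with the pipeline.
Its single pruning step is itself LP-based (reactions whose single
deletion defeats the target must appear in every subset). Guards: at most
20 reactions and 500k subsets. The test suite compares pipeline and oracle
on 200 seeded networks of up to 15 reactions; an independent GLPK
formulation additionally cross-checks the biomass LP.

## Numerical choices

* LP and MILP solved with HiGHS (scipy.optimize); solver determinism is
  not assumed — the contract is the solution *set*.
* Default flux bound magnitude 1000 mmol/gDW·h when unspecified; uptake
  limits override upper bounds. Finite bounds double as the big-M
  coefficients of the binary linking constraints.
* Mass-balance tolerance 1e-6 (componentwise on |S·v|); biomass-target
  comparisons at 1e-6; blocked-reaction threshold 1e-9; binaries read at
  0.5; objectives compared as integers after rounding (norms are
  integers).
* Flux vectors attached to solutions have inactive-reaction entries
  zeroed; active entries are the solver's witness.
* Degenerate inputs: networks without a depth-1 frontier, empty integer
  cuts, unreachable biomass targets and over-budget oracle calls raise
  typed errors; infeasible LPs are signalled distinctly from zero optima.

## Known limitations

* Multi-group substitution is not implemented; the MILP recursion covers
  those optima at MILP cost.
* Phase 1 classifies by whole-network LPs; the depth-based subnetwork
  decomposition that accelerates classification on genome-scale models is
  not implemented, so very large models lean on the MILP more heavily.
* Grouping is structural only; flux-coupled but structurally unrelated
  reactions (detectable by null-space methods) are not grouped, which
  costs binaries but never correctness.
* Thermodynamic plausibility of enumerated sets (cycles, extreme cofactor
  fluxes) is not scored; inspect the attached flux vectors.
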