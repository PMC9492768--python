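# Methods

## Model and premise

`boolpath` treats a clustered scRNA-seq population as samples from the
state space of a synchronous Boolean network whose wiring is given by a
signed prior-knowledge network (PKN). Nodes are genes; a directed edge
carries sign +1 (activation) or −1 (inhibition). Under synchronous update
every node recomputes its state from the previous global state, so the
dynamics are deterministic on a finite state space and every trajectory
ends in a fixed point or a limit cycle (an attractor). The working
hypothesis is that observed cell states lie on or near these attractors,
which is what makes rule inference from cross-sectional data possible at
all — no time series is needed.

## Rule grammar

Each node's update function is restricted to **read-once AND/OR
expressions** over non-empty subsets of its signed regulators: each
regulator appears at most once, as a positive literal for an activator and
a negated literal for an inhibitor. Every such function is unate (monotone
per input after sign folding) and non-constant. The candidate space is
enumerated, deduplicated by truth table, and sorted by canonical expression
string; its sizes — 1, 4, 17 for in-degree 1, 2, 3 — are computed by
enumeration, never hard-coded, and are checked in the tests against an
independent oracle that composes truth tables directly. The three-input
majority function is unate but not read-once and is intentionally outside
the space; admitting all unate functions (18 at k = 3) was considered and
rejected for parsimony — read-once forms match the AND/OR gate semantics of
curated pathway diagrams. Nodes with no surviving regulators hold their
state (identity rule), acting as boundary conditions. In-degree is capped
at 3; over-connected nodes keep the three parents with the largest
|Spearman correlation| between parent and target binarized columns
(zero-variance columns count as 0, ties break alphabetically), a
data-driven but deterministic selection.

## Inference

The fit of a complete rule set is the attractor-mismatch error summed over
cells (see README for the formula); cells with identical binary states
share one simulation, so the cost scales with the number of *distinct*
observed states. Global search is a genetic algorithm over vectors of
candidate indices: population 24, up to 50 generations with early stop
after 10 stagnant ones, tournament selection (size 3), uniform crossover
(probability 0.7), per-position mutation (0.1), one elite. Two
implementation details matter in practice:

- **Multi-start.** Three independently seeded populations are run (stopping
  early on a zero-error hit) and the best kept. Single runs occasionally
  stall on deceptive landscapes where two coupled nodes must change
  together.
- **Exact search at toy scale.** When the whole rule-set product space is
  smaller than one GA run's evaluation budget (pop × generations), it is
  enumerated exactly instead — strictly cheaper and optimal by
  construction. Realistic pathways are far beyond this bound and always use
  the GA.

The node-wise local search then visits nodes in descending out-degree
(ties alphabetical), scoring every candidate of a node by the
node-restricted error with all other rules fixed; the argmin set is the
**equivalent rule set (ERS)**. The incumbent keeps its current rule
whenever that rule is itself minimal — swapping rules mid-sweep would
perturb the context later nodes are scored in — and the sweep is repeated
(at most 5 times) until no rule changes, a plain coordinate descent. The
ERS reported is the one computed in the final, stable context. A node is
"optimized" if its ERS is a strict subset of its candidate space; a pathway
is optimized if any node is.

## Downstream statistics

*Uncertainty factor* U = (|max ERS| − |obs ERS| + 1)/|max ERS|: 1 when the
data pinned the rule down to one candidate, 1/|max ERS| when it excluded
nothing. *Importance* clamps each node ON (knock-in) and OFF (knock-out),
simulates from every observed cell state, and accumulates the L1 distance
between the two attractors' cycle-averaged state vectors over **all**
nodes, including the clamped one (taking only the clamped node's own
coordinate would make the distance degenerate), times U, scaled to [0, 1]
per network by the maximum. Simulation uses each node's simplest ERS member
(fewest AND terms, then fewest literals, then lexicographic) — ERS
multiplicity enters through U, not through averaging over rule sets.

For a two-group contrast, RA (|difference of group means|), σ (population
standard deviation across all cells of the cluster) and log2 fold change
(pseudocount 0.01) are computed on the retained **continuous** expression,
not the binary states (configurable); the pathway modulation metric is
M = Σ RA·σ·I over pathway genes, with genes absent from the data
contributing zero and being listed in the report. Significance is by
resampling with the add-one estimator p = (1 + #{M\* ≥ M})/(B + 1), B =
1000 by default. The default scheme permutes cell group labels and
recomputes RA (σ and I fixed); an alternative resamples the observed RA
values across genes with replacement. Label permutation is the default
because it has an exact exchangeability justification and calibrates at
nominal level in simulation; both schemes are recorded in the output.
Bonferroni correction runs over every pathway tested, and the reported
significant list is further restricted to optimized pathways, since an
unconstrained rule space means the importance weights carry no information
from the data. Direction is the sign of the summed log2 fold changes.

*Attractor analysis* samples 10 rule sets node-wise uniformly from the ERS,
adds the simplest-rule set, simulates from every observed cell state under
each, and deduplicates the reached attractors by a rotation-minimal
canonical key. Cells are assigned to the attractor minimizing the Hamming
distance (minimum over cycle states, restricted to network genes), ties to
the smallest canonical key so assignment is order-independent. Before the
chi-square association tests (Pearson, no continuity correction) attractors
with fewer than 5 assigned cells are pooled into an "other" category for
validity of the asymptotics.

## Synthetic data generator

A scenario fixes a random signed network (edge probability 0.25–0.35 in the
shipped experiments, 30% inhibitory edges, in-degree ≤ 3 by construction,
weakly connected), a ground-truth rule set drawn uniformly from each node's
candidate space, and a two-group population: each cell picks an attractor
(per-group mixture weights, uniform by default), one cycle state uniformly,
then flips each bit independently with probability `flip_noise` (default
0.05 — the scale of droplet dropout in presence/absence terms). Continuous
expression is binary × (base 2.0 + a per-gene uniform(0.5, 1.5) baseline +
any group mean shift) × lognormal(0, 0.3) noise; zeros stay zero, matching
the dropout-dominated bimodality of droplet data that also motivates the
default nonzero binarization. Cells are split round-robin into 4
pseudo-subjects per group, mirroring a small two-arm cohort so
subject-level contingency tables have a realistic shape.

What the generator does **not** emulate: UMI count distributions, library
size variation, batch effects, doublets, ambient RNA, or genes outside the
network. Passing tests therefore demonstrate correctness of the inference
machinery under the model's own premise (cells near attractors, noise
bitwise-independent), not robustness to every artifact of real droplet
chemistry.

## Verification battery and problem sizes

The shipped experiments (tests and `scripts/acceptance.py`) use sizes
chosen so the whole battery runs in about a minute while keeping each
statistical check properly powered: 5-node/in-degree-≤2 toys for exhaustive
optimality checks (product space ≤ 4⁵), 8-node networks with 200 cells for
rule recovery (noise-free) and the pathway contrast (flip 0.05, shift 2.0
on target-pathway genes, 100 cells per group, B = 500, 20 replicates),
10-node networks for attractor assignment (pooled accuracy over 20
replicates), and 10 replicates of the 1%/50%/100%/200% training-fraction
harness. The ERS-plateau property (no significant inflation from 100% to
50% of cells) is asserted at 400-cell populations: the plateau is a
saturation phenomenon, and 200 cells are past the point where the distinct
observed states stop adding constraints for 8-node networks.

## Numerical and degenerate-input choices

- Cycle detection hashes visited states, so limit cycles are found exactly;
  the traditional 100-step budget is kept as a guard and as the default
  simulation horizon.
- State vectors order nodes alphabetically, frozen at network build; all
  tie-breaks (regulator selection, ERS ordering, attractor assignment) are
  lexicographic, making every stage deterministic given its seed.
- Duplicate PKN edges merge; on conflicting signs inhibition wins, with a
  warning. KGML relation subtypes without sign semantics (binding,
  indirect effect) default to activation with a warning, or are dropped in
  strict mode. Gene symbols are uppercased on ingest.
- Pathways retaining fewer than 15 data-covered nodes are skipped
  (degenerate statistics otherwise); the bound is configurable.
- All-zero importance vectors are left as zeros rather than rescaled; a
  constant gene (σ = 0) contributes nothing to M; the add-one p-value
  estimator keeps p > 0.

## Known limitations

- Read-once rules cannot express threshold-like logic (majority); if the
  underlying biology needs it, the nearest read-once rule is learned
  instead.
- The ERS is computed in the context of one incumbent rule set; rules that
  fit only in a *different* zero-error context can be missed, which is the
  main source of the few-percent shortfall from perfect rule recovery.
- Synchronous update is a modeling convention; asynchronous semantics can
  have different attractor structure and are out of scope.
- The chi-square association tests treat cells as independent; within-
  subject correlation is not modeled.
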