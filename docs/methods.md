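# Methods

## Model class and update semantics

`mtmap` operates on Boolean networks: each node carries one logical update
rule over AND/OR/NOT and the constants 0/1, read and written in the BoolNet
`targets, factors` dialect (`!`, `&`, `|`). Node declaration order is fixed
and defines bit positions, so states are encoded as integers and printed as
0/1 strings in declaration order; all outputs are reproducible run to run.

Updates are **asynchronous**: from a state, a single node whose rule value
disagrees with its current state flips. We select uniformly among *eligible*
flips only. Sampling the updated node among all nodes (including those whose
rule already agrees) inserts self-loop steps that do not change hitting
probabilities or which attractor is reached, so the two schemes agree on
every quantity computed here; eligible-only selection simply avoids wasted
steps. A state with no eligible flip is a fixed point; attractors in general
are the terminal strongly connected components (SCCs) of the asynchronous
state-transition graph (STG).

A sustained intervention (a drug) is modeled by **pinning**: the target
node's rule is replaced by the constant 1 (ON) or 0 (OFF), so its state can
never change.

Multi-level read-outs (e.g. graded survival outputs) are encoded as nested
threshold indicators `X_geq_1 .. X_geq_L`, one per level; level conditions
must be nested (level l implies level l−1) or the encoding is rejected. A
phenotype weight on the multi-level node is split uniformly over its
indicators, so the summed indicator preference equals the weight times the
normalized level.

## Attractor identification

Attractor search first simplifies the network by **constant propagation**:
rules that simplify to constants are substituted into their dependents until
a fixed point. This preserves attractors exactly — a node with a constant
rule takes that value in every attractor. The residual network's STG is then
enumerated exhaustively (default cap: 24 free nodes, and enumeration is only
attempted below 2^20 states) and terminal SCCs are extracted; above the cap
the caller supplies seed states and the search is restricted to their
reachable closure, which yields every attractor reachable from the seeds.
Every reported attractor is re-verified to be closed under the full
network's asynchronous successors.

## Basins of attraction and phenotype preference

The basin fraction of an attractor is the probability that a uniformly
random initial state, evolved by uniformly random asynchronous updates,
converges to it. When the full state space is no larger than the sample
budget (default 10,000 states), basins are computed *exactly* as the mean
absorption probability of the induced Markov chain over all initial states
(sparse linear solve); this is the quantity the sampling estimator
approximates, computed deterministically. Otherwise we sample the requested
number of distinct initial states without replacement and trace one random
trajectory from each (step budget 10,000·N); trajectories that fail to reach
a known attractor are counted as censored, and a censored fraction above 1%
is an error since it indicates an incomplete attractor set.

Phenotype preference of an attractor is the marker-weighted mean state over
its states, averaged **uniformly** over the states of a complex attractor
(not over its stationary distribution); positive weights mark desirable
read-outs (antisurvival), negative weights undesirable ones (prosurvival),
normalized by total absolute weight to [−1, 1].

## The merged transition map

Pinning the given target deforms the attractor landscape; the merged
transition map (MTM) collects exactly the transitions this enables:

* **regulated segments** — from each original attractor, the reachable STG
  of the pinned network, seeded with the attractor's states *with the pin
  applied* (the drug fixes the target instantaneously, so the pinned node
  never flips inside a regulated segment), absorbed at the pinned network's
  attractor states;
* **reversal segments** — from each pinned-landscape attractor, the
  reachable STG of the unpinned network (drug withdrawal), absorbed at the
  original attractor states. Segments whose seeds are already absorbing are
  retained as trivial (identity) segments.

Branch probabilities are uniform over a state's outgoing transitions. Each
(source attractor, destination attractor) pair of a segment is a **path
ensemble** carrying: the absorption probability, the expected per-node flip
counts conditional on that destination, the phenotypic-preference sign
pp = sign(pref(dest) − pref(source)), the landscape type (+1 regulated,
−1 reversal), and a significance equal to the source attractor's basin
fraction on its own landscape.

Asynchronous STGs contain cycles, so enumerating literal transition paths
diverges. Absorption probabilities and conditional expected flip counts are
instead computed in closed form by absorbing-Markov-chain first-step
analysis (sparse LU on I − Q), which equals the branch-probability-weighted
sum over all paths. A seeded Monte-Carlo trajectory sampler over the same
segments is kept as an independent oracle; the test suite checks agreement
at 10,000 trajectories per contested segment.

## Scoring and partner selection

The literal weighted flipping frequency of node n is

    wff(n) = Σ_ensembles significance · P(absorb) · E[flips_n | absorbed] · pp · type

and is reported per node together with its full per-ensemble decomposition.
For *ranking* partner candidates the package separates the unsigned flip
mass by the sign of the preference change and orders candidates by the
**conflict score**

    conflict(n) = undesired_mass(n) − desired_mass(n),

the net flip mass concentrated on preference-decreasing transitions. The
node that flips most specifically while the network slides toward worse
phenotypes is the state-conflict transmitter; nodes that flip broadly on
desired and undesired paths alike cancel out. This choice was made because
the selection target is explicitly the node flipping most frequently in
undesired paths, and because on the shipped conflict fixtures the |wff| and
signed-wff orderings top a motif follower node whose pinning is not optimal
under the exhaustive perturbation oracle, while the conflict score uniquely
tops the interconnecting node, whose pinning is optimal. All four ranking
modes (`conflict`, `undesired`, `wff`, `abs`) are selectable. Candidates
exclude the given target, pinned inputs, and phenotype markers; ties break
lexicographically. The default list length is 5.

The **control type** of a selected partner is chosen by signal-flow
analysis on the signed interaction graph (signs from exact per-regulator
monotonicity testing; non-monotone dependencies contribute both signs):

    influence(t) = Σ_{L=1..Lmax} α^L Σ_{paths of length L} Π sign / Π out-degree

computed by damped matrix powers with α = 0.5 and Lmax = the structural
diameter. The partner is pinned *opposite* to its propagated tendency under
the given perturbation, which blocks the conflict channel instead of
reinforcing it. A zero tendency is reported as undetermined, with the
recommendation to evaluate both pin types exhaustively. The damping value,
out-degree normalization and path-length cap are this package's
concretization of topological signal flow; results on the fixtures are
insensitive to α in (0, 1) because sign, not magnitude, is consumed.

## Multi-stable motifs and interconnecting nodes

Mutually inhibiting motifs necessarily lie in one *maximal* SCC (two-way
paths merge components), so maximal-SCC decomposition cannot separate them.
Motifs are therefore identified as **minimal strongly connected subgraphs**:
simple directed cycles (length ≤ 4 by default) whose edge signs can multiply
to +1 — negative loops cannot hold alternative stable states — and whose
projections onto the supplied attractor states (per state for complex
attractors) show at least two distinct patterns. Candidates are accepted
smallest-first and node-disjointly, which drops composite loops such as the
double-negative conflict loop spanning both motifs.

Interconnecting nodes between two motifs are the interior nodes of
k-shortest loopless directed paths (default k = 10) between the motif node
sets, ranked by number of covering paths, then earliest covering path
length, then name. A motif pair is a **conflict pair** when the best
unambiguous net path sign is negative in both directions. The genome-scale
census counts unordered pairs of node-disjoint positive loops (size ≤ 3)
with mutual net-negative connections of length ≤ 2, built by joining
enumerated cycles; it matches brute-force subgraph enumeration on small
graphs in the test suite.

Degree-preserving randomization performs double-edge swaps — (u→x), (v→y)
become (u→y), (v→x), the sign traveling with its source edge — rejecting
self-loops and duplicate signed edges, until ⌈fraction·|E|⌉ swaps succeed.
In/out degree sequences are preserved exactly.

Interaction-table curation merges signed-directed tables, drops unsigned or
undirected rows, optionally applies a cross-validation whitelist of
(source, target) pairs, and returns the largest weakly connected component.

## Baselines

Control effectiveness of a pin set is the basin-weighted mean phenotype
preference of the pinned network minus the same quantity for the reference
network (unperturbed by default; optionally the given-target-only network
for synergy-specific reporting). SPS evaluates every candidate (node, ON/OFF)
added to the given pin exhaustively and is the brute-force optimum the MTM
ranking is checked against. The minimum feedback vertex set is computed
exactly by iterative-deepening branch-and-bound on shortest cycles (self-loop
nodes always included) up to 30 nodes, with a flagged greedy heuristic above;
FVS pin values are taken from the desired attractor's states, and suggested
sets of size ≥ 2 are assessed by the mean effectiveness over all node pairs.

## Synthetic fixtures: what they emulate, and what they do not

The conflict fixture realizes the canonical adaptive-resistance topology:
a drug node T (OFF until pinned ON) activates two positive-feedback motifs
at once — a desired (apoptotic) motif y1..yn and an undesired (survival)
motif g1..gm — which inhibit each other mutually, one direction directly
(y1 ⊣ g1) and the other through a relay chain i1..id (the interconnecting
nodes); markers Ma = y1 ∧ ¬g1 (weight +1) and Mp = g1 (weight −1) read out
the phenotype. Pinning T alone triggers a race (competitive stabilization)
that ends heterogeneously: from the quiescent attractor the desired outcome
is reached with probability 2/3 and the undesired one with 1/3 in the
default instance. Additionally pinning the interconnect OFF makes the
desired outcome the unique response. The exemplar variant adds a
drug-driven side motif (saturates ON under the pin) and an untouched side
motif gated by the desired motif, so the pinned network converges to
exactly three attractors.

These fixtures are minimal: every inter-attractor transition flips most
participating nodes about once, so the *raw* all-path flip ratio does not
single out the interconnect (the winning motif's nodes flip as often on
desired paths); the interconnect dominates on undesired paths and in the
conflict-weighted score, and the tests assert exactly that. Real disease
networks are larger, have wider in-degree distributions, multiple input
nodes, and complex attractors; passing on these fixtures demonstrates the
algorithmic contracts (oracle agreement, optimality on the designed ground
truth), not predictive performance on any real signaling model. Random
networks for property testing draw per-node in-degrees around a requested
mean (clipped to [1, 4]) with random truth tables at a configurable ON bias.

## Numerical choices and degenerate inputs

* Absorption probabilities per (source, label) sum to 1 within 1e−9; the
  linear systems are solved by sparse LU.
* Preference differences are rounded to 12 decimals before taking the pp
  sign, so float noise cannot flip a genuinely neutral ensemble.
* Ensembles with pp = 0 are retained with zero ranking contribution, so
  flip-mass totals remain auditable.
* Attractor ids are assigned by sorted minimal state key; all orderings and
  tie-breaks are lexicographic; every stochastic routine takes an explicit
  seed, and identical configurations produce byte-identical outputs.
* State-space enumeration is budgeted (default 2^22 visited states) and
  exceeding the budget raises a capacity error naming the budget, rather
  than degrading silently.
* Degenerate cases are errors with explanations: empty models, undeclared
  or duplicate nodes, all-zero score rankings, zero signal-flow tendency,
  segments with unreachable absorbing sets, too-few swappable edges.

## Known limitations

* Exhaustive attractor search is limited to ~20 free residual nodes; larger
  models require seed states and recover only seed-reachable attractors
  (sufficient for the MTM, whose segments start at attractors, but not a
  proof of attractor completeness).
* Only single-node given perturbations are supported in the MTM driver;
  multi-target given treatments are future work.
* Stable-motif-control (succession-diagram) baselines are out of scope.
* The signal-flow control-type rule presumes the conflict reaches the
  candidate through the undesired channel; for candidates with genuinely
  balanced dual-sign paths it abstains rather than guessing.
* Complex attractors weight their states uniformly in preference and in
  motif projections; the asynchronous stationary distribution is not used.
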