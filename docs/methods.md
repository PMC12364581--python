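# Methods

## Model

A regulatory network is a labelled, signed, real-weighted adjacency
matrix: entry (i, j) is the influence of node i **onto** node j
(positive = activation, negative = inhibition, 0 = none).  This
orientation is load-bearing — a directed-influence test in the suite
pins it down, because the edge-list convention is easy to transpose.

**Boolean (Ising) dynamics.**  States are vectors in {−1, +1}^n; −1 is
chosen for the low state (rather than 0) so that a low regulator still
contributes to its targets.  One *time step* updates a single node,
drawn uniformly at random among the non-clamped nodes: the node takes
the sign of its weighted input sum and holds its current value when the
sum is exactly zero.  The hold rule is exact and never randomized.  A
state is a fixed point when no single-node update changes it; the test
is exact, so the simulator evaluates it only every n steps (pure cost
amortization).  Trajectories that have not fixed after `max_steps`
(default 1000) single-node updates are discarded; relative frequencies
are normalized over the converged remainder, with the converged fraction
reported separately so that the two normalizations are interconvertible.
The "one update = one time step" reading of the step cap is
configurable, since a cap counted in full sweeps is the other plausible
convention.

**Multi-level dynamics.**  Each node takes one of 2l values
{±k/l : k = 1..l} (l = 1 recovers the Boolean space; l = 2 is the
four-level model).  The update of node j computes
s = Σᵢ Adjᵢⱼ·xᵢ / dⱼ, with dⱼ the number of nonzero incoming weights
(self-edges included; this definition makes l = 1 collapse exactly onto
the Boolean rule), and maps |s| ∈ ((k−1)/l, k/l] to level k with the
sign of s, holding on s = 0.  Right-closed brackets are deliberate: the
states they admit at exact boundaries (e.g. all-nodes-at-±½ copies of
Boolean fixed points in a two-team network) are genuine fixed points of
this rule.  Internally levels are integers and all comparisons are
integer arithmetic, so bracket boundaries are never subject to
floating-point error.  Nodes with no regulators hold their value (with a
warning).  Multi-level simulation is intended for team networks; it runs
on any integer-weighted network but is untested territory beyond teams.

**Team scores and discretization.**  A team's score in a state is the
mean expression of its members.  For profile labels (22000-style),
node expressions are first normalized by the largest |value| attained —
by default within each state, optionally across the whole run — and a
team maps to symbol 2 at exactly +1, 0 at exactly −1, and 1 strictly
between.  Per-state normalization is the default because the multi-level
fixed-point set contains uniformly scaled-down copies of coarser-level
fixed points; normalizing within the state identifies each such copy
with its fully polarized pattern, and it is the only reading under which
the three team-network observations (two-team: no new configurations;
three-team: partial expression in ≥ 2 teams; five-team: ≥ 99% polarized
profiles) hold simultaneously.  The run-level normalization is kept as
an option for comparison.

**Interventions.**  Asymmetric weight W scales the focal node's outgoing
(off-diagonal) weights *only while that node is high*; it is implemented
inside the input-sum assembly rather than by mutating the adjacency, so
Monte-Carlo simulation, exhaustive enumeration, transition graphs and
perturbation analysis all share one code path.  W = 1 is bitwise the
identity.  Cytokines are extra nodes with no incoming regulation,
clamped at +1 and excluded from the update draw; since their input sum
is identically zero, clamping coincides with the hold rule for a high
initialization and simply makes the constitutive activation explicit and
independent of initial-condition sampling.  Frequency statistics (F(k),
F_A(1)) always count core nodes only.

**MBF counting.**  Decreasing monotone functions of s inputs are
enumerated as complemented increasing functions, built by depth-first
assignment over the input lattice in popcount order (output 0 is allowed
at a point only when all its immediate predecessors are 0).  This visits
exactly the D(s) monotone functions instead of filtering all 2^(2^s)
truth tables, and is cross-checked against the Dedekind numbers
(2, 3, 6, 20, 168, 7581 for s = 0..5) and, for small n, against a
brute-force tally over all function tuples.  Truth tables are integer
bitmasks in lexicographic input order; permutation invariance of the
toggle makes the canonical input (1..1, 0..0) sufficient for the u/v
counts.  Sizes n ≥ 7 raise an explicit infeasibility error (D(6) ≈
7.8·10⁶ functions per node and the tuple space is a product over nodes);
no sampling fallback is provided.

## Defaults and parameters

| Parameter | Default | Rationale |
| --- | --- | --- |
| initial conditions | 100 000 (API) / 10 000 (tests, scans, acceptance) | the F(k) landmarks checked at ±0.02 have binomial SE ≤ 0.005 at 10⁴ |
| max updates per trajectory | 1000 | pure toggles fix within tens of updates; the cap only matters for the non-converging self-inhibition circuits |
| replicates | 3, mean ± 95% normal CI | matches the error-bar convention of the frequency analyses |
| threshold grids | W ∈ {1..10}, W_C ∈ {0..10} | integer grids; saturation F_A(1) = 1 is detected with tolerance 10⁻⁶ since runs that reach it reach it exactly |
| impurity caps | 100 non-isomorphic variants (n ≤ 5), 50 (n = 6) | combination counts explode beyond; when enumerable (< 2·10⁵ combinations) all are tested then capped, otherwise combinations are sampled without replacement before filtering |
| embedding | size ∈ {10, 15, 20}, density ∈ {2, 4, 6}, 100 hosts | host = uniform simple digraph with size·density edges, no self-loops, reciprocal edges allowed; host weights uniform on {−1, +1}; every ordered cross pair uniform on {−1, 0, +1} |
| unequal teams | multinomial(total = n·m̂, equal cells), rejecting any zero-size or mean-size team | the mean-size rejection is implemented literally, which is why m̂ = 1 is infeasible |

All randomness flows from a single root seed through `SeedSequence`
spawning: replicates, grid cells and replicate networks get independent,
reproducible child streams, and identical seeds give bit-identical
outputs.

## What the generators emulate — and what they do not

The synthetic families (toggles, impurity variants, team networks,
random-host embeddings) probe the *structural* claim that mutual
inhibition stabilizes half-high co-expression states.  They are
deliberately idealized: no autoregulatory heterogeneity, no
hierarchical or scale-free host topology, no time-varying weights, no
transcription/translation kinetics.  Edge weights are relative,
dimensionless abstractions of interaction strength.  Passing tests
therefore certify the combinatorial and dynamical claims about these
idealized circuits — not that any measured biological network will
realize them quantitatively.  The T-helper fixture is transcribed from
reported pairwise regulator interactions (16 of 20 inhibitions present)
and the cytokine wiring uses a generic activate-own/inhibit-others
pattern with two documented sign exceptions (IFN-γ activates FOXP3;
TGF-β activates RORC), exposed as an override table because the full
interaction matrix is not settled; conclusions drawn from it are
sensitive to those choices.

## Numerical and design notes

- Fixed-point checks use `x_j · input_j ≥ 0` over updatable nodes; with
  integer weights this is exact, and with U(0,1) weights ties have
  measure zero.
- Degenerate inputs: an empty edge file is an error; a single team is
  allowed (all-activation clique); odd-n self-inhibition toggles
  legitimately return an empty distribution with converged fraction 0.
- Isomorphism filtering of impurity variants reduces each variant to the
  unweighted digraph of its activations (keeping all nodes, so the
  zero-activation case compares correctly) and uses networkx VF2
  matching.
- State-transition graphs classify a non-fixed state as *metastable*
  when removing its self-regulation contributions would make it fixed —
  the inter-node wiring sustains the pattern while a self-edge drives it
  away.  This operationalizes the observation that states stable without
  self-regulation acquire outgoing transitions under self-inhibition.
- Single-bit (Hamming) perturbation outcomes for even toggles are exact
  three-way ties (return probability 1/3 for the tetrahedron); the suite
  asserts that returning is a modal outcome rather than a strict
  majority, which the tie structure rules out.
- The `.topo` dialect is sign-only by design; real-valued weights
  round-trip through a JSON sidecar so the topology files stay
  interchangeable with other tools.  A header row is required on write
  and tolerated-if-absent on read (with a warning).

## Known limitations

- The activating-only cytokine analysis: under the implemented update
  rule, exact enumeration shows the focal-only state becomes the unique
  fixed point at signalling strength 2 for even toggles (the competing
  half-high state's input to the focal node is W_C − 1), not 4; the
  odd-toggle threshold 3 and all edge-weight and activate-and-inhibit
  thresholds are reproduced.  The acceptance suite asserts the full
  published-style table and the even-n entry fails honestly.
- MBF analysis covers pure toggles only (no self-regulation, teams or
  impurities) and stops at n = 6.
- Exhaustive state enumeration is capped at 22 free nodes; the
  multi-level enumerator at 4·10⁶ states.
- Monte-Carlo support equality with the exhaustive oracle is only
  guaranteed when every basin is sampled; the suite checks networks of
  ≤ 12 nodes at 10⁴ initial conditions, where the smallest observed
  basin frequencies are ≥ 1%.
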