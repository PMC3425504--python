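# Methods

## Model and assumptions

The engine simulates a population of myopic agents on an undirected simple
graph, each trying to form one matched pair with a neighbour. The state is
a configuration of preference pointers: `p(v)` is the single outstanding
proposal of node `v` (or null), and the matching is the set of mutual
pairs `{(u,v) : p(u)=v, p(v)=u}`. Nodes observe only their own status and
their neighbours' matched/unmatched status plus proposals addressed to
them; they know nothing of the global topology.

The behavioural core is **prudence**: a matched node does not act at all
unless at least one *unmatched* neighbour proposes to it. When the gate
fires, it accepts uniformly at random among its current partner and the
unmatched proposers (partner retained with probability 1/(k+1) against k
proposers). Unmatched nodes hold their pointer with probability λ and
otherwise follow the preference cascade: proposers first (uniform), then
unmatched neighbours, then matched neighbours; isolated nodes clear their
pointer.

### Synchronous conflict resolution

The model prescribes per-node behaviour but not simultaneous-update
semantics. The engine resolves a round in two phases from a single
round-start snapshot:

1. every matched node whose gate fires runs its acceptance rule; if it
   accepts an external proposer, that proposer's pointer is *locked* for
   the round, so the new pair forms atomically (a **swap**);
2. every unlocked unmatched node runs the unmatched rule; two free
   neighbours that select each other form a new pair (an **add**).

With this acceptance lock every round decomposes into add and swap events,
which makes the matching-size monotonicity a structural invariant of the
engine rather than a statistical tendency: under pure prudence the size
can never decrease, and the engine raises an error if it ever does. A
displaced partner keeps its now-dangling pointer (it still encodes the
node's current preference) until it acts as an unmatched node in a later
round; this gives the displaced node a standing claim to swap back, which
is what makes the free "particles" diffuse rather than march.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `keep_prob` (λ) | probability an unmatched node holds its pointer for a round | 0.2 | outcomes are practically insensitive to λ in (0,1); see below for λ=0 |
| `nonprudent_prob` (β) | probability a matched node with no proposers but free neighbours breaks its pair by proposing to one | 0.0 | the minimal non-prudent variant; β>0 voids the monotonicity invariant |
| `seed` | engine RNG seed | — | trajectories are bit-identical for identical (graph, init, params) |
| `max_rounds` | censoring cap per run | 10 000 | censoring is always explicit in trajectories and result tables |

**λ = 0 is degenerate.** With no hold probability, synchronized proposal
cycles can rotate deterministically forever (on the 4-cycle from the empty
configuration, all four nodes can chase each other's proposals in a
2-periodic orbit). The hold probability is the symmetry breaker;
self-stabilization holds for λ ∈ (0,1), and λ=0 is safe only on
structurally forced instances such as a single edge.

## Graph families

* `make_bad_graph(n)` — the bipartite half-graph, sides `a1..an`,
  `b1..bn`, edge `a_i–b_j` iff `i ≥ j` (n(n+1)/2 edges, `deg a_i = i`,
  `deg b_j = n−j+1`). Exact enumeration verifies that the horizontal edges
  are its unique perfect matching for every tested n. This construction is
  the canonical bipartite graph with that uniqueness property; its
  triangular structure produces the exponential slowdown measured below.
* `make_ring(n)` — the n-cycle, the bounded-degree reference family.
* `make_small_world(n, k=4, p=0.1)` / `make_preferential_attachment(n, m=2)` —
  connected Watts–Strogatz and Barabási–Albert generators (networkx),
  rejection-resampled with incremented seeds until a perfect matching
  exists, since the game is only well posed on such graphs. Defaults give
  sparse connected 24-node-scale networks. The BA growth starts from a
  complete graph on m nodes so that saturated attachment (m = n−1) yields
  the complete graph.
* `make_random_pm_graph(n, bipartite, multiplicity, extra_edges)` — a
  planted perfect matching `(v1,v2),(v3,v4),…` plus uniformly drawn extra
  edges, rejection-sampled into the requested class (bipartite or not;
  unique or multiple perfect matchings, verified by exact counting). The
  class membership, not the sampling path, is the contract.

## Exact analytics and guards

Maximum matching size delegates to the blossom algorithm (networkx
`max_weight_matching`, max-cardinality); an independent include/exclude
enumeration oracle in the test suite anchors it on random corpora.
Perfect-matching counting recurses on a lowest-degree node (guard: ≤ 24
nodes); matching enumeration is exhaustive (guard: ≤ 16 nodes); the
matching-level Markov chain is built in full (guard: ≤ 12 nodes) with
uniform transition probabilities over a state's eligible moves, maximum
matchings absorbing, and expected hitting times solved as a dense linear
system. Within each size class the transition relation is verified
symmetric (reversibility).

The shortest augmenting path is found by exact iterative-deepening search
over simple alternating paths (lexicographic tie-break for the witness).
This is exponential in the worst case but exact on general graphs —
deliberate, because a layered BFS can miss shortest paths through odd
cycles, and a too-long "shortest" length would overstate the k/(k+1)
quality bound. Maximality of the matching is checked first (via the
blossom size), so "no augmenting path" is decided without search.

## Experiments

All experiment seeds derive from a master seed and the run's coordinates
via `numpy.random.SeedSequence`, making every table exactly reproducible
and resumable. Desk-scale defaults are 20 graphs × 100 runs per point
(the full 100 × 1000 protocol is a parameter choice away); censored runs
enter means at the cap and are always counted explicitly.

* **Ring scaling** (`ring_scaling_report`): mean rounds to a
  1/2-approximate matching over n = 8…128, 500 runs per size; the per-size
  means are fit against `log n` and against `n`, and the growth is called
  sublinear when the log model's R² is at least the linear model's
  (a constant sequence is flagged degenerate and counts as sublinear).
  Fixed-threshold verdicts are used instead of hypothesis tests because
  the underlying statements are asymptotic growth classes.
* **Bad-graph slowdown** (`bad_graph_scaling_report`): mean rounds to the
  unique perfect matching from a uniformly sampled near-perfect start with
  one free node per side. For side sizes ≤ 7 starts are sampled uniformly
  from the exhaustively enumerated family; for larger sides from the
  constructive pivot family (horizontal edges shifted down by one below a
  uniform pivot p, leaving `a1` and `b_p` free). Growth is called
  geometric when every successive ratio of means exceeds 1. Measured
  ratios rise with n (≈1.8 at sides 5→6, ≈2.0 by sides 7→8), consistent
  with an asymptotically geometric law whose base is not yet saturated at
  the smallest sides.
* **Slow-start fraction** (`bad_matching_fraction`): in a balanced
  bipartite graph every (n−1)-matching leaves exactly one free node per
  side, so the opposite-side fraction is identically 1. The informative
  statistic is the `strict=True` variant — the fraction whose free pair is
  non-adjacent, hence not completable in a single augmentation — which is
  (2ⁿ−n−1)/(2ⁿ−1), strictly increasing to 1: almost every near-perfect
  matching is a slow start.
* **Topology comparison** (`topology_comparison`): small-world,
  preferential-attachment and bad-graph families at a common node count
  (default 24), empty starts, round cap 2000 — set two orders of magnitude
  above what the small-world family needs at that size. Confidence
  intervals bootstrap the per-graph means (the experiment's top-level
  unit); the ordering verdict is reported as inconclusive when adjacent
  intervals overlap rather than failing the run. The bad graph is a
  single deterministic instance per size, so its "graphs" differ only in
  run seeds.

Measured at 24 nodes (master seed 0): small-world ≈ 49 rounds to maximum,
preferential attachment ≈ 81, bad graph ≈ 564 with ~4 % of runs censored
at the cap, while the median time to a 1/2-approximate matching is ≈ 3
rounds for all three families — the "approximate quickly, perfect slowly"
gap. Note the bad-graph and preferential-attachment run-length
distributions overlap at this size (the bad graph's minimum is a few
dozen rounds, PA's tail reaches ~500), so no cap cleanly separates
"never finishes" from "finishes"; clean exponential separation emerges
from side ≈ 16 (mean ≈ 3300 rounds) upward.

## What the synthetic conditions do and do not show

The generators reproduce the structural conditions of the studied game —
balanced perfect-matching-admitting networks of the four families at
24-node scale — not any empirical social network: degree heterogeneity
beyond Barabási–Albert, weighted or costly ties, and asynchronous human
timing are all outside the model. Passing tests therefore validate the
algorithmic predictions (growth classes, orderings, invariants), not
behavioural fidelity to any particular human population. The engine is
synchronous and memoryless by design; the memory-based variant and any
human-seconds-per-round calibration are out of scope.

## Known limitations

* Enumeration guards cap the exact analytics (24/16/12 nodes); the
  simulator itself has no such cap.
* The shortest-augmenting-path search is exact but exponential in the
  worst case; it is an analytic tool, not part of the dynamics.
* `make_random_pm_graph` can exhaust its retry budget for near-infeasible
  classes (e.g. unique perfect matching with many extra edges); it fails
  with a diagnostic rather than silently relaxing the request.
* With β > 0 the monotonicity invariant is intentionally disabled; sizes
  may oscillate and runs may not terminate before the cap.
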