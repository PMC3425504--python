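# prudent-matching

Agent-based simulation and exact analysis of the **distributed maximum
matching game**: individuals on a network try to pair up with neighbours,
seeing only whether each neighbour is currently matched, with everyone
rewarded for the total number of pairs. The package implements the
*prudence* dynamics — a matched node never abandons its partner unless an
unmatched neighbour proposes to it — together with the graph families,
exact matching analytics and experiment harness needed to study when such
myopic local coordination succeeds and when it stalls.

It is aimed at researchers in collective behaviour, distributed computing
and network science who want a reproducible desk-scale laboratory for
matching dynamics.

## The model

Each node `v` holds a single preference pointer `p(v)` — the one neighbour
it currently proposes to (or null). Mutual pointers form matched pairs, and
the matching `M` is the set of mutual pairs. Time is synchronous: each
round every node observes the round-start state and updates its pointer.

* **Unmatched nodes** keep their pointer with probability λ (default 0.2);
  otherwise they accept a proposer uniformly at random, failing that
  propose to a uniform unmatched neighbour, failing that to a uniform
  matched neighbour.
* **Matched nodes** act only when an unmatched neighbour proposes to them
  (*prudence*), then accept uniformly among their current partner and the
  proposers — so with k proposers the pair survives with probability
  1/(k+1).

Viewed at the matching level the dynamics are a Markov chain whose moves
either **add** an edge between two free nodes or **swap** an edge in for an
adjacent matched edge; |M| never decreases, and the process self-stabilizes
to a maximum matching from any start (for λ ∈ (0,1)).

The quality of an intermediate matching is controlled by its shortest
augmenting path: if no augmenting path of length ≤ 2k+1 exists, then
|M| ≥ k/(k+1) · |M*|. Half-good matchings therefore appear in a few rounds,
while the *bad graph* — the bipartite half-graph `a_i ~ b_j iff i ≥ j`,
whose horizontal edges `a_i–b_i` are its unique perfect matching — needs
exponentially many rounds to finish: almost every near-perfect matching
leaves two free nodes that must random-walk through the triangular
structure before they can meet.

## Worked example

```python
from prudent_matching import EngineParams, make_small_world, rounds_to_ratio, run

G = make_small_world(24, k=4, p=0.1, seed=7)
traj = run(G, init=None, params=EngineParams(keep_prob=0.2, seed=42), stop="maximum")
print(traj.rounds, traj.sizes)
```

Running `python examples/02_prudence_run.py` prints:

```
small-world n=24 (k=4, p=0.1): maximum matching size 12
run finished: reached_target after 12 rounds
matching size by round: [0, 3, 7, 8, 9, 10, 10, 11, 11, 11, 11, 11, 12]
  first round with a 0.5-approximate matching: 2
  first round with a 0.83-approximate matching: 5
  first round with a 1-approximate matching: 12
```

Half of the maximum matching is found after 2 rounds; the final pair —
the resolution of the last augmenting path — takes as long as everything
before it. The other scripts in `examples/` show the bad graph's unique
perfect matching and slow starts (`01`), exact hitting times on the
matching-level Markov chain (`03`), and the growth-class sweeps (`04`).

## Command line

```
prudent-matching generate --model badgraph --n 12 -o bad.edges
prudent-matching simulate bad.edges --seed 1 --stop maximum -o run1
prudent-matching experiment --preset topology -o results/
prudent-matching analyze results/results.csv
```

`generate` writes plain-text edge lists (plus a JSON metadata sidecar),
`simulate` writes a per-round trajectory CSV and a summary JSON, and
`experiment` runs the preset suites (`ring-scaling`, `bad-scaling`,
`bad-fraction`, `topology`) or a YAML-specified grid.

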