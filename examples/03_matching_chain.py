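"""The matching-level Markov chain and exact expected hitting times.

The prudence dynamics, viewed at the matching level, move by two kinds of
transition: add an edge between two free nodes, or swap an edge in for a
neighbouring matched edge.  On small graphs the full chain can be built
and the expected number of moves to reach a maximum matching solved
exactly as a linear system.
"""

import networkx as nx

from prudent_matching import build_matching_chain

C6 = nx.relabel_nodes(nx.cycle_graph(6), {i: f"v{i + 1}" for i in range(6)})
chain = build_matching_chain(C6)

sizes = [len(s) for s in chain.states]
print(f"C6: {len(chain.states)} matchings "
      f"({sizes.count(0)} empty, {sizes.count(1)} single, "
      f"{sizes.count(2)} double, {sizes.count(3)} perfect)")
print(f"transitions: {len(chain.transitions)}; "
      f"reversible within size classes: {chain.is_reversible_within_size()}")
print(f"expected moves to a maximum matching from the empty matching: "
      f"{chain.hitting_time_from([]):.3f}")
print(f"... and from the worst matching: "
      f"{max(chain.expected_hitting_times()):.3f}")
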