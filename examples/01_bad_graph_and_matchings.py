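"""The bad graph: unique perfect matching and slow near-perfect starts.

Builds the bipartite half-graph on sides a1..an / b1..bn (a_i ~ b_j iff
i >= j), verifies by exact enumeration that the horizontal edges are its
only perfect matching, and measures how many of its near-perfect matchings
are "slow" starting states for local matching dynamics.
"""

from prudent_matching import (
    bad_matchings,
    count_perfect_matchings,
    hk_bound,
    make_bad_graph,
    shortest_augmenting_path,
)
from prudent_matching.experiments import bad_matching_fraction

n = 6
G = make_bad_graph(n)
print(f"bad graph, side size {n}: {G.number_of_nodes()} nodes, {G.number_of_edges()} edges")
print(f"perfect matchings: {count_perfect_matchings(G)}  (the horizontal edges a_i-b_i)")

# the fully shifted near-perfect matching: a_{i+1}-b_i, leaving a1 and bn free
M = frozenset((f"a{i + 1}", f"b{i}") for i in range(1, n))
assert M in set(bad_matchings(n))
rep = shortest_augmenting_path(G, M)
print(f"\nworst near-perfect matching: {sorted(M)}")
print(f"shortest augmenting path: {rep.shortest_length} edges -> quality bound "
      f"{hk_bound(rep.shortest_length)} of maximum")

# how common are slow starts among near-perfect matchings?
print(f"\nfraction of (n-1)-matchings with one free node per side: "
      f"{bad_matching_fraction(n)}")
print(f"fraction whose free pair is non-adjacent (not fixable in one step): "
      f"{bad_matching_fraction(n, strict=True)}")
print("\nThe non-adjacent fraction approaches 1 with n: almost every "
      "near-perfect matching is an exponentially slow start.")
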