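"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms (and
networkx matching routines): maximum matching by exhaustive include/exclude
recursion over the edge list, matchings by subset filtering.  They anchor
the correctness of the fast paths on small graphs.
"""

from __future__ import annotations

import itertools
from random import Random

import networkx as nx
import pytest


def brute_force_max_matching_size(G: nx.Graph) -> int:
    """Exhaustive maximum-matching size by include/exclude over edges."""
    edges = list(G.edges())

    def rec(i: int, used: set) -> int:
        best = 0
        for j in range(i, len(edges)):
            u, v = edges[j]
            if u in used or v in used:
                continue
            used.add(u)
            used.add(v)
            best = max(best, 1 + rec(j + 1, used))
            used.discard(u)
            used.discard(v)
        return best

    return rec(0, set())


def brute_force_matchings_of_size(G: nx.Graph, s: int) -> set[frozenset]:
    """All size-s matchings by filtering all s-subsets of the edge set."""
    edges = [tuple(sorted(e)) for e in G.edges()]
    out = set()
    for combo in itertools.combinations(edges, s):
        nodes = [x for e in combo for x in e]
        if len(set(nodes)) == 2 * s:
            out.add(frozenset(combo))
    return out


def random_graph(rng: Random, n_min: int = 4, n_max: int = 10) -> nx.Graph:
    """A random labelled graph with string nodes, varied density."""
    n = rng.randint(n_min, n_max)
    p = rng.choice([0.2, 0.35, 0.5, 0.7])
    G = nx.Graph()
    G.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                G.add_edge(f"n{i}", f"n{j}")
    return G


def random_configuration(G: nx.Graph, rng: Random) -> dict:
    """An arbitrary preference-pointer configuration (not necessarily a matching)."""
    pref = {}
    for v in sorted(G.nodes()):
        nbrs = sorted(G.neighbors(v))
        pref[v] = rng.choice(nbrs) if nbrs and rng.random() < 0.7 else None
    return pref


@pytest.fixture
def path4() -> nx.Graph:
    """Path a-b-c-d."""
    G = nx.Graph()
    G.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return G


@pytest.fixture
def single_edge() -> nx.Graph:
    G = nx.Graph()
    G.add_edge("a", "b")
    return G
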