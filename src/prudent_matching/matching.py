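"""Exact matching analytics.

Validation, maximum-matching size, maximality, approximation ratios,
shortest augmenting paths with the k/(k+1) quality bound, exact
perfect-matching counting, matching enumeration, and the matching-level
Markov chain whose hitting times describe how local matching dynamics
approach a maximum matching.

Enumeration-based operations carry explicit size guards: they are exact
oracles for desk-scale graphs, not scalable algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np

__all__ = [
    "MatchingError",
    "AugPathReport",
    "MatchingChain",
    "normalize_matching",
    "matched_nodes",
    "validate_matching",
    "assert_valid_matching",
    "maximum_matching_size",
    "is_maximal",
    "approximation_ratio",
    "shortest_augmenting_path",
    "hk_bound",
    "count_perfect_matchings",
    "enumerate_matchings",
    "all_matchings",
    "bad_matchings",
    "build_matching_chain",
    "read_matching",
    "write_matching",
]

Edge = tuple[str, str]


class MatchingError(ValueError):
    pass


def _edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


def normalize_matching(M: Iterable) -> frozenset[Edge]:
    """Canonicalize an iterable of node pairs to a frozenset of sorted tuples."""
    return frozenset(_edge(*e) for e in M)


def matched_nodes(M: Iterable) -> set[str]:
    return {x for e in M for x in e}


def validate_matching(G: nx.Graph, M: Iterable) -> Optional[str]:
    """Return ``None`` if ``M`` is a valid matching of ``G``, else a diagnostic.

    A matching is a set of edges of the graph no two of which share an
    endpoint; the diagnostic names the offending node or non-edge.
    """
    seen: set[str] = set()
    for e in normalize_matching(M):
        u, v = e
        if not G.has_edge(u, v):
            return f"pair ({u}, {v}) is not an edge of the graph"
        for x in (u, v):
            if x in seen:
                return f"node {x} is covered by more than one matching edge"
            seen.add(x)
    return None


def assert_valid_matching(G: nx.Graph, M: Iterable) -> frozenset[Edge]:
    msg = validate_matching(G, M)
    if msg is not None:
        raise MatchingError(msg)
    return normalize_matching(M)


def maximum_matching_size(G: nx.Graph) -> int:
    """Exact maximum-matching cardinality (blossom algorithm, general graphs)."""
    return len(nx.max_weight_matching(G, maxcardinality=True))


def is_maximal(G: nx.Graph, M: Iterable) -> bool:
    """True iff no edge of ``G`` has both endpoints uncovered by ``M``."""
    M = assert_valid_matching(G, M)
    covered = matched_nodes(M)
    return all(u in covered or v in covered for u, v in G.edges())


def approximation_ratio(G: nx.Graph, M: Iterable, max_size: Optional[int] = None) -> Fraction:
    """|M| / maximum matching size, as an exact fraction (1 on edgeless graphs)."""
    M = assert_valid_matching(G, M)
    if max_size is None:
        max_size = maximum_matching_size(G)
    if max_size == 0:
        return Fraction(1)
    return Fraction(len(M), max_size)


@dataclass(frozen=True)
class AugPathReport:
    """Shortest augmenting path of a matching.

    ``shortest_length`` is the minimum odd number of edges over all
    augmenting paths (``None`` when the matching is maximum);
    ``witness_path`` is one lexicographically-first path of that length.
    """

    shortest_length: Optional[int]
    witness_path: Optional[tuple[str, ...]]


def shortest_augmenting_path(
    G: nx.Graph, M: Iterable, max_size: Optional[int] = None
) -> AugPathReport:
    """Find a shortest augmenting path for ``M`` in ``G``.

    An augmenting path alternates unmatched/matched edges, starts and ends
    at free nodes, and has odd length; flipping it grows the matching by
    one.  The search is an exact iterative-deepening enumeration of simple
    alternating paths (exponential worst case; intended for the desk-scale
    graphs the analytics run on).  Returns ``shortest_length=None`` exactly
    when ``M`` is maximum.
    """
    M = assert_valid_matching(G, M)
    if max_size is None:
        max_size = maximum_matching_size(G)
    if len(M) >= max_size:
        return AugPathReport(None, None)

    partner: dict[str, str] = {}
    for u, v in M:
        partner[u] = v
        partner[v] = u
    adj = {v: sorted(G.neighbors(v)) for v in G}
    free = sorted(v for v in G if v not in partner)

    def dfs(x: str, depth: int, limit: int, path: list[str], visited: set[str]) -> bool:
        if depth == limit:
            return x not in partner
        if depth % 2 == 0:  # next edge must be unmatched
            for y in adj[x]:
                if y in visited or partner.get(x) == y:
                    continue
                visited.add(y)
                path.append(y)
                if dfs(y, depth + 1, limit, path, visited):
                    return True
                path.pop()
                visited.remove(y)
        else:  # next edge must be the matched edge at x
            y = partner.get(x)
            if y is not None and y not in visited:
                visited.add(y)
                path.append(y)
                if dfs(y, depth + 1, limit, path, visited):
                    return True
                path.pop()
                visited.remove(y)
        return False

    for length in range(1, 2 * len(M) + 2, 2):
        for s in free:
            path = [s]
            if dfs(s, 0, length, path, {s}):
                return AugPathReport(length, tuple(path))
    raise RuntimeError("matching below maximum but no augmenting path found")


def hk_bound(shortest_length: Optional[int]) -> Fraction:
    """Matching-quality guarantee from the shortest augmenting-path length.

    A matching with no augmenting path of length 2k+1 or shorter has size
    at least k/(k+1) of the maximum; a matching with no augmenting path at
    all is maximum (bound 1).
    """
    if shortest_length is None:
        return Fraction(1)
    if shortest_length < 1 or shortest_length % 2 == 0:
        raise ValueError(f"augmenting-path length must be a positive odd integer, got {shortest_length}")
    k = (shortest_length - 1) // 2
    return Fraction(k, k + 1)


def count_perfect_matchings(G: nx.Graph, _guard: int = 24) -> int:
    """Exact number of perfect matchings, by recursion on a lowest-degree node.

    Guarded to graphs with at most 24 nodes; beyond that, use an
    alternating-cycle test for uniqueness instead of counting.
    """
    if len(G) > _guard:
        raise ValueError(
            f"count_perfect_matchings enumerates exactly and is limited to {_guard} nodes "
            f"(got {len(G)}); for larger graphs test uniqueness via alternating cycles"
        )
    if len(G) % 2:
        return 0
    adj = {v: set(G.neighbors(v)) for v in G}
    active = set(adj)

    def rec() -> int:
        if not active:
            return 1
        v = min(active, key=lambda x: (len(adj[x] & active), x))
        nbrs = sorted(adj[v] & active)
        if not nbrs:
            return 0
        active.discard(v)
        total = 0
        for u in nbrs:
            active.discard(u)
            total += rec()
            active.add(u)
        active.add(v)
        return total

    return rec()


def _enumerate(G: nx.Graph, size: Optional[int], guard: int, name: str) -> list[frozenset[Edge]]:
    if len(G) > guard:
        raise ValueError(f"{name} is exhaustive and limited to {guard} nodes (got {len(G)})")
    edges = sorted(_edge(u, v) for u, v in G.edges())
    out: list[frozenset[Edge]] = []
    cur: list[Edge] = []
    used: set[str] = set()

    def rec(start: int) -> None:
        if size is None:
            out.append(frozenset(cur))
        elif len(cur) == size:
            out.append(frozenset(cur))
            return
        for j in range(start, len(edges)):
            u, v = edges[j]
            if u in used or v in used:
                continue
            cur.append(edges[j])
            used.add(u)
            used.add(v)
            rec(j + 1)
            cur.pop()
            used.discard(u)
            used.discard(v)

    rec(0)
    return out


def enumerate_matchings(G: nx.Graph, size: int) -> list[frozenset[Edge]]:
    """All matchings of ``G`` with exactly ``size`` edges (graphs up to 16 nodes)."""
    if size < 0:
        raise ValueError("size must be non-negative")
    return _enumerate(G, size, guard=16, name="enumerate_matchings")


def all_matchings(G: nx.Graph, _guard: int = 16) -> list[frozenset[Edge]]:
    """Every matching of ``G`` including the empty one (graphs up to 16 nodes)."""
    return _enumerate(G, None, guard=_guard, name="all_matchings")


def bad_matchings(n: int) -> list[frozenset[Edge]]:
    """All (n-1)-matchings of the bad graph with one free node on each side.

    These are the near-perfect starting states from which reaching the
    unique perfect matching takes exponentially many rounds: the two free
    nodes sit on opposite sides of the bipartition and must drift through
    the triangular structure before they can pair up.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if n > 8:
        raise ValueError("bad_matchings enumerates exhaustively and is limited to n <= 8")
    from .graphs import make_bad_graph

    G = make_bad_graph(n)
    out = []
    for M in enumerate_matchings(G, n - 1):
        free = set(G) - matched_nodes(M)
        if len({x[0] for x in free}) == 2:  # one 'a' node and one 'b' node
            out.append(M)
    return out


@dataclass
class MatchingChain:
    """Markov chain over the matchings of a graph.

    States are all matchings; a transition picks an edge (u, v) with at
    least one free endpoint and either adds it (both free) or swaps it in
    for the matched partner edge (exactly one matched).  Transitions never
    shrink the matching, and within a size class the relation is
    symmetric.  Transition probabilities are uniform over the eligible
    moves of a state; maximum matchings are absorbing.
    """

    graph: nx.Graph
    states: list[frozenset[Edge]]
    index: dict[frozenset[Edge], int]
    transitions: list[tuple[int, int, str]]  # (from, to, "add" | "swap")
    max_size: int

    def out_moves(self, i: int) -> list[int]:
        return [j for (a, j, _k) in self.transitions if a == i]

    def is_reversible_within_size(self) -> bool:
        """Check that every same-size (swap) transition has its reverse."""
        pairs = {(a, b) for (a, b, k) in self.transitions if k == "swap"}
        return all((b, a) in pairs for (a, b) in pairs)

    def expected_hitting_times(self) -> np.ndarray:
        """Expected rounds to absorption in the set of maximum matchings.

        Solves (I - Q) t = 1 over the transient states; entries for
        absorbing (maximum) states are 0.
        """
        m = len(self.states)
        transient = [i for i, s in enumerate(self.states) if len(s) < self.max_size]
        pos = {i: r for r, i in enumerate(transient)}
        q = np.zeros((len(transient), len(transient)))
        outs: dict[int, list[int]] = {i: [] for i in transient}
        for a, b, _k in self.transitions:
            if a in pos:
                outs[a].append(b)
        for i in transient:
            moves = outs[i]
            if not moves:
                raise RuntimeError("transient state with no moves; chain cannot absorb")
            p = 1.0 / len(moves)
            for j in moves:
                if j in pos:
                    q[pos[i], pos[j]] += p
        t = np.linalg.solve(np.eye(len(transient)) - q, np.ones(len(transient)))
        full = np.zeros(m)
        for i, r in pos.items():
            full[i] = t[r]
        return full

    def hitting_time_from(self, M: Iterable) -> float:
        M = assert_valid_matching(self.graph, M)
        return float(self.expected_hitting_times()[self.index[M]])

    def export_states_and_transitions(self, states_path, transitions_path) -> None:
        """Write (state-id, size) and (from-id, to-id, kind) CSVs."""
        with open(states_path, "w") as fh:
            fh.write("state_id,size,edges\n")
            for i, s in enumerate(self.states):
                fh.write(f"{i},{len(s)},{';'.join(f'{u}-{v}' for u, v in sorted(s))}\n")
        with open(transitions_path, "w") as fh:
            fh.write("from_id,to_id,kind\n")
            for a, b, k in self.transitions:
                fh.write(f"{a},{b},{k}\n")


def build_matching_chain(G: nx.Graph) -> MatchingChain:
    """Build the full matching-level chain of ``G`` (graphs up to 12 nodes)."""
    if len(G) > 12:
        raise ValueError("build_matching_chain enumerates all matchings; limited to 12 nodes")
    states = sorted(all_matchings(G), key=lambda s: (len(s), sorted(s)))
    index = {s: i for i, s in enumerate(states)}
    edges = sorted(_edge(u, v) for u, v in G.edges())
    transitions: list[tuple[int, int, str]] = []
    for i, M in enumerate(states):
        covered = matched_nodes(M)
        partner = {}
        for u, v in M:
            partner[u] = v
            partner[v] = u
        for u, v in edges:
            fu, fv = u not in covered, v not in covered
            if fu and fv:
                transitions.append((i, index[M | {(u, v)}], "add"))
            elif fu != fv:
                w = u if fv else v  # the matched endpoint
                old = _edge(w, partner[w])
                transitions.append((i, index[(M - {old}) | {(u, v)}], "swap"))
    return MatchingChain(G, states, index, transitions, max_size=maximum_matching_size(G))


def write_matching(M: Iterable, path) -> None:
    """Write a matching as 'u v' lines."""
    lines = ["# matching: one 'u v' pair per line"]
    lines += [f"{u} {v}" for u, v in sorted(normalize_matching(M))]
    Path(path).write_text("\n".join(lines) + "\n")


def read_matching(path, G: Optional[nx.Graph] = None) -> frozenset[Edge]:
    """Read a matching pair list; validated against ``G`` when given."""
    pairs = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise MatchingError(f"{path}:{lineno}: expected 'u v', got {raw!r}")
        pairs.append((parts[0], parts[1]))
    M = normalize_matching(pairs)
    if len(M) < len(pairs):
        raise MatchingError(f"{path}: duplicate pairs in matching file")
    if G is not None:
        return assert_valid_matching(G, M)
    return M
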