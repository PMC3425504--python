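"""Graph families for the distributed matching game.

All generators return :class:`networkx.Graph` objects with string node
labels.  ``G.graph["meta"]`` records the generator name, its parameters and
the seed actually used, and bipartite families additionally carry
``G.graph["bipartition"]`` as a pair of node-label tuples.  Stochastic
families that must admit a perfect matching enforce this by rejection
sampling: the generator is re-run with an incremented seed until a perfect
matching exists (the matching game is only well posed on such graphs).
"""

from __future__ import annotations

import json
from pathlib import Path
from random import Random

import networkx as nx

from . import matching as _matching

__all__ = [
    "GraphGenerationError",
    "make_bad_graph",
    "make_ring",
    "make_small_world",
    "make_preferential_attachment",
    "make_random_pm_graph",
    "read_edge_list",
    "write_edge_list",
]

#: Cap on rejection-sampling attempts before a generator gives up.
MAX_ATTEMPTS = 1000


class GraphGenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the requested constraints."""


def _has_perfect_matching(G: nx.Graph) -> bool:
    if G.number_of_nodes() % 2:
        return False
    return 2 * len(nx.max_weight_matching(G, maxcardinality=True)) == G.number_of_nodes()


def _require_even(n: int, what: str = "n") -> None:
    if n % 2:
        raise ValueError(f"{what} must be even (a perfect matching is required), got {n}")


def make_bad_graph(n: int) -> nx.Graph:
    """Bipartite half-graph on sides ``a1..an`` and ``b1..bn``.

    ``a_i`` is adjacent to ``b_j`` exactly when ``i >= j``.  The n
    "horizontal" edges ``(a_i, b_i)`` form the unique perfect matching.
    Near-perfect matchings that leave one node free on each side behave
    like two particles that must traverse the triangular edge structure
    before they can meet, which makes the last augmentation exponentially
    slow for local matching dynamics.
    """
    if n < 1:
        raise ValueError(f"side size must be a positive integer, got {n}")
    G = nx.Graph()
    a = [f"a{i}" for i in range(1, n + 1)]
    b = [f"b{j}" for j in range(1, n + 1)]
    G.add_nodes_from(a)
    G.add_nodes_from(b)
    for i in range(1, n + 1):
        for j in range(1, i + 1):
            G.add_edge(f"a{i}", f"b{j}")
    G.graph["bipartition"] = (tuple(a), tuple(b))
    G.graph["meta"] = {"generator": "badgraph", "n": n}
    return G


def make_ring(n: int) -> nx.Graph:
    """Cycle ``C_n`` on nodes ``v1..vn``; ``n`` must be even so that a
    perfect matching (alternate edges) exists."""
    if n < 4:
        raise ValueError(f"ring needs n >= 4, got {n}")
    _require_even(n)
    G = nx.Graph()
    nodes = [f"v{i}" for i in range(1, n + 1)]
    G.add_nodes_from(nodes)
    for i in range(n):
        G.add_edge(nodes[i], nodes[(i + 1) % n])
    G.graph["meta"] = {"generator": "ring", "n": n}
    return G


def _relabel(G: nx.Graph) -> nx.Graph:
    return nx.relabel_nodes(G, {i: f"v{i + 1}" for i in G.nodes()})


def make_small_world(n: int, k: int = 4, p: float = 0.1, seed: int = 0) -> nx.Graph:
    """Connected Watts-Strogatz graph on ``n`` nodes admitting a perfect matching.

    ``k`` nearest neighbours on the ring lattice, rewiring probability
    ``p``.  Resampled with an incremented seed until a perfect matching
    exists.
    """
    _require_even(n)
    if k % 2 or k < 2:
        raise ValueError(f"k must be a positive even integer, got {k}")
    if k >= n:
        raise ValueError(f"k must be smaller than n (got k={k}, n={n})")
    if not 0 <= p <= 1:
        raise ValueError(f"rewiring probability must lie in [0, 1], got {p}")
    for attempt in range(MAX_ATTEMPTS):
        H = _relabel(nx.connected_watts_strogatz_graph(n, k, p, tries=200, seed=seed + attempt))
        if _has_perfect_matching(H):
            H.graph["meta"] = {
                "generator": "smallworld", "n": n, "k": k, "p": p,
                "seed": seed, "seed_used": seed + attempt,
            }
            return H
    raise GraphGenerationError(
        f"no perfect matching found in {MAX_ATTEMPTS} Watts-Strogatz samples "
        f"(n={n}, k={k}, p={p}, seed={seed})"
    )


def make_preferential_attachment(n: int, m: int = 2, seed: int = 0) -> nx.Graph:
    """Barabasi-Albert graph on ``n`` nodes (each new node attaches ``m``
    edges; growth starts from a complete graph on ``m`` nodes, so saturated
    attachment ``m = n - 1`` yields ``K_n``), resampled until a perfect
    matching exists."""
    _require_even(n)
    if not 1 <= m < n:
        raise ValueError(f"need 1 <= m < n, got m={m}, n={n}")
    for attempt in range(MAX_ATTEMPTS):
        H = _relabel(
            nx.barabasi_albert_graph(
                n, m, seed=seed + attempt, initial_graph=nx.complete_graph(m)
            )
        )
        if _has_perfect_matching(H):
            H.graph["meta"] = {
                "generator": "pa", "n": n, "m": m,
                "seed": seed, "seed_used": seed + attempt,
            }
            return H
    raise GraphGenerationError(
        f"no perfect matching found in {MAX_ATTEMPTS} Barabasi-Albert samples "
        f"(n={n}, m={m}, seed={seed})"
    )


def make_random_pm_graph(
    n: int,
    bipartite: bool = True,
    multiplicity: str = "unique",
    extra_edges: int = 4,
    seed: int = 0,
) -> nx.Graph:
    """Random graph with a planted perfect matching, classified by structure.

    The perfect matching ``(v1,v2), (v3,v4), ...`` is planted, then
    ``extra_edges`` further edges are drawn uniformly.  Candidates are
    resampled until the graph falls in the requested class:

    * ``bipartite=True``  -- sides are the odd- and even-indexed nodes and
      extra edges cross them; ``bipartite=False`` requires the sampled
      graph to actually contain an odd cycle.
    * ``multiplicity`` -- ``"unique"`` (exactly one perfect matching) or
      ``"multiple"`` (at least two), verified by exact counting.
    """
    _require_even(n)
    if n > 24:
        raise ValueError("exact perfect-matching classification is limited to n <= 24")
    if multiplicity not in ("unique", "multiple"):
        raise ValueError(f"multiplicity must be 'unique' or 'multiple', got {multiplicity!r}")
    if extra_edges < 0:
        raise ValueError("extra_edges must be non-negative")

    nodes = [f"v{i}" for i in range(1, n + 1)]
    planted = [(nodes[2 * i], nodes[2 * i + 1]) for i in range(n // 2)]
    if bipartite:
        side_a = nodes[0::2]
        side_b = nodes[1::2]
        pool = [(u, v) for u in side_a for v in side_b if (u, v) not in planted]
    else:
        pool = [
            (nodes[i], nodes[j])
            for i in range(n) for j in range(i + 1, n)
            if (nodes[i], nodes[j]) not in planted
        ]
    if extra_edges > len(pool):
        raise ValueError(f"extra_edges={extra_edges} exceeds the {len(pool)} available edges")

    rng = Random(seed)
    for attempt in range(MAX_ATTEMPTS):
        G = nx.Graph()
        G.add_nodes_from(nodes)
        G.add_edges_from(planted)
        G.add_edges_from(rng.sample(pool, extra_edges))
        if bipartite != nx.is_bipartite(G):
            continue
        count = _matching.count_perfect_matchings(G)
        if (multiplicity == "unique") != (count == 1):
            continue
        if bipartite:
            G.graph["bipartition"] = (tuple(nodes[0::2]), tuple(nodes[1::2]))
        G.graph["meta"] = {
            "generator": "random-pm", "n": n, "bipartite": bipartite,
            "multiplicity": multiplicity, "extra_edges": extra_edges,
            "seed": seed, "attempts": attempt + 1,
        }
        return G
    raise GraphGenerationError(
        f"could not realize a {'bipartite' if bipartite else 'non-bipartite'} graph with a "
        f"{multiplicity} perfect matching in {MAX_ATTEMPTS} attempts "
        f"(n={n}, extra_edges={extra_edges}); relax extra_edges or the multiplicity class"
    )


class EdgeListError(ValueError):
    """Malformed edge-list file; the message carries the offending line number."""


def write_edge_list(G: nx.Graph, path, meta_path=None) -> None:
    """Write ``G`` as a plain-text edge list.

    One ``u v`` line per edge; isolated nodes appear as singleton lines so
    the node set round-trips.  If ``meta_path`` is given, generator
    metadata and any bipartition are written there as JSON.
    """
    path = Path(path)
    lines = ["# edge list: one 'u v' per line; singleton lines declare isolated nodes"]
    for u, v in sorted(tuple(sorted(e)) for e in G.edges()):
        lines.append(f"{u} {v}")
    for v in sorted(nx.isolates(G)):
        lines.append(str(v))
    path.write_text("\n".join(lines) + "\n")
    if meta_path is not None:
        payload = {
            "meta": G.graph.get("meta"),
            "bipartition": [list(s) for s in G.graph["bipartition"]]
            if "bipartition" in G.graph else None,
        }
        Path(meta_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_edge_list(path, meta_path=None) -> nx.Graph:
    """Read a graph written by :func:`write_edge_list`.

    Raises :class:`EdgeListError` (with the line number) on malformed
    lines, self-loops or duplicate edges.
    """
    path = Path(path)
    G = nx.Graph()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 1:
            G.add_node(parts[0])
        elif len(parts) == 2:
            u, v = parts
            if u == v:
                raise EdgeListError(f"{path}:{lineno}: self-loop on node {u!r}")
            if G.has_edge(u, v):
                raise EdgeListError(f"{path}:{lineno}: duplicate edge {u!r} {v!r}")
            G.add_edge(u, v)
        else:
            raise EdgeListError(f"{path}:{lineno}: expected 'u v' or a singleton node, got {raw!r}")
    if meta_path is not None:
        payload = json.loads(Path(meta_path).read_text())
        if payload.get("meta") is not None:
            G.graph["meta"] = payload["meta"]
        if payload.get("bipartition"):
            G.graph["bipartition"] = tuple(tuple(s) for s in payload["bipartition"])
    return G
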