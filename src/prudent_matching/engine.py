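"""Synchronous round-based engine for the prudence matching game.

Each node holds a single preference pointer ``pref[v]`` — the one
neighbour it currently proposes to (or ``None``).  Two neighbours that
point at each other form a matched pair, and the matching of a
configuration is the set of such mutual pairs.  Time advances in
synchronous rounds: every node observes the round-start snapshot of the
network and updates its pointer.

The behavioural rule is *prudence*: a matched node never abandons its
partner unless an unmatched neighbour proposes to it.  Unmatched nodes
prefer neighbours who proposed to them over other unmatched neighbours,
and unmatched neighbours over matched ones; with probability ``keep_prob``
they simply hold their current pointer for the round.

Simultaneous updates are resolved with an *acceptance lock*: when a
matched node accepts an external proposer in phase 1, the proposer's
pointer is frozen for the round, so the new pair forms atomically and
every round is a sequence of "add" and "swap" events.  Under pure
prudence (``nonprudent_prob == 0``) the matching size is therefore
non-decreasing, and the engine asserts this invariant at every round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from random import Random
from typing import Iterable, Optional, Union

import networkx as nx
import pandas as pd

from .matching import assert_valid_matching, maximum_matching_size

__all__ = [
    "EngineParams",
    "Snapshot",
    "Trajectory",
    "PrudenceViolation",
    "init_configuration",
    "make_snapshot",
    "unmatched_behavior",
    "matched_behavior",
    "step_round",
    "run",
    "rounds_to_ratio",
]

Configuration = dict[str, Optional[str]]


class PrudenceViolation(RuntimeError):
    """The engine observed a matching-size decrease under pure prudence."""


@dataclass(frozen=True)
class EngineParams:
    """Behavioural parameters of the engine.

    keep_prob
        Probability that an unmatched node holds its current pointer for a
        round instead of acting (the algorithm's outcome is practically
        insensitive to this value; 0.2 by default).
    nonprudent_prob
        Probability that a matched node with no proposers but at least one
        unmatched neighbour breaks its pair by proposing elsewhere.  0
        (pure prudence) by default.
    """

    keep_prob: float = 0.2
    nonprudent_prob: float = 0.0
    seed: int = 0
    max_rounds: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.keep_prob <= 1.0:
            raise ValueError(f"keep_prob must lie in [0, 1], got {self.keep_prob}")
        if not 0.0 <= self.nonprudent_prob <= 1.0:
            raise ValueError(f"nonprudent_prob must lie in [0, 1], got {self.nonprudent_prob}")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be positive")


@dataclass(frozen=True)
class Snapshot:
    """Round-start view of the network: who is matched with whom, and the
    pending proposals of unmatched nodes."""

    adj: dict[str, list[str]]
    pref: Configuration
    partner: dict[str, str]
    proposers: dict[str, list[str]]


def _adjacency(G: nx.Graph) -> dict[str, list[str]]:
    return {v: sorted(G.neighbors(v)) for v in sorted(G.nodes())}


def init_configuration(G: nx.Graph, M: Optional[Iterable] = None) -> Configuration:
    """Configuration realizing matching ``M``: matched nodes point at their
    partner, all others at nothing."""
    pref: Configuration = {v: None for v in sorted(G.nodes())}
    if M:
        for u, v in assert_valid_matching(G, M):
            pref[u] = v
            pref[v] = u
    return pref


def make_snapshot(G_or_adj: Union[nx.Graph, dict], pref: Configuration) -> Snapshot:
    adj = G_or_adj if isinstance(G_or_adj, dict) else _adjacency(G_or_adj)
    partner: dict[str, str] = {}
    proposers: dict[str, list[str]] = {}
    for u, p in pref.items():
        if p is None:
            continue
        if pref[p] == u:
            partner[u] = p
        else:
            proposers.setdefault(p, []).append(u)
    return Snapshot(adj, pref, partner, proposers)


def matching_of(pref: Configuration) -> frozenset[tuple[str, str]]:
    """The matching realized by a configuration (mutual preference pairs)."""
    return frozenset(
        (u, p) for u, p in pref.items() if p is not None and u < p and pref[p] == u
    )


def unmatched_behavior(v: str, snap: Snapshot, keep_prob: float, rng: Random) -> Optional[str]:
    """New pointer for unmatched node ``v``.

    With probability ``keep_prob`` the pointer is unchanged.  Otherwise
    ``v`` accepts a proposer uniformly at random if it has any; failing
    that it proposes to a uniform unmatched neighbour; failing that to a
    uniform matched neighbour; an isolated node clears its pointer.
    """
    if keep_prob > 0.0 and rng.random() < keep_prob:
        return snap.pref[v]
    props = snap.proposers.get(v)
    if props:
        return props[rng.randrange(len(props))] if len(props) > 1 else props[0]
    partner = snap.partner
    unmatched = [u for u in snap.adj[v] if u not in partner]
    if unmatched:
        return unmatched[rng.randrange(len(unmatched))] if len(unmatched) > 1 else unmatched[0]
    matched = [u for u in snap.adj[v] if u in partner]
    if matched:
        return matched[rng.randrange(len(matched))] if len(matched) > 1 else matched[0]
    return None


def matched_behavior(v: str, snap: Snapshot, rng: Random) -> str:
    """Accepted neighbour for matched node ``v``: uniform over its current
    partner and its unmatched proposers.

    May only be invoked under the prudence gate — at least one unmatched
    neighbour proposing to ``v`` — otherwise the matched node does not act
    at all.
    """
    props = snap.proposers.get(v)
    if not props:
        raise RuntimeError(
            "matched_behavior called without an unmatched proposer; "
            "prudence forbids the node from acting"
        )
    candidates = [snap.partner[v]] + props
    return candidates[rng.randrange(len(candidates))]


def _step(
    adj: dict[str, list[str]],
    pref: Configuration,
    params: EngineParams,
    rng: Random,
) -> tuple[Configuration, tuple[int, int, int]]:
    """One synchronous round; returns (new configuration, (proposals,
    acceptances, switches)).  ``pref`` is not mutated."""
    snap = make_snapshot(adj, pref)
    partner, proposers = snap.partner, snap.proposers
    new = dict(pref)
    locked: set[str] = set()
    proposals = acceptances = switches = 0
    beta = params.nonprudent_prob

    # Phase 1: matched nodes with proposers may switch; the accepted
    # proposer is locked, consummating the new pair this round.
    for v in partner:
        if v in proposers:
            choice = matched_behavior(v, snap, rng)
            if choice != partner[v]:
                new[v] = choice
                locked.add(choice)
                switches += 1
                acceptances += 1
        elif beta > 0.0:
            free_nbrs = [u for u in adj[v] if u not in partner]
            if free_nbrs and rng.random() < beta:
                new[v] = free_nbrs[rng.randrange(len(free_nbrs))]
                proposals += 1

    # Phase 2: unlocked unmatched nodes act from the same snapshot.
    for v in adj:
        if v in partner or v in locked:
            continue
        nv = unmatched_behavior(v, snap, params.keep_prob, rng)
        if nv != pref[v]:
            if nv is not None and pref.get(nv) == v:
                acceptances += 1
            else:
                proposals += 1
        new[v] = nv
    return new, (proposals, acceptances, switches)


def step_round(
    G: Union[nx.Graph, dict], config: Configuration, params: EngineParams, rng: Random
) -> Configuration:
    """Advance one synchronous round and return the new configuration."""
    adj = G if isinstance(G, dict) else _adjacency(G)
    new, _counts = _step(adj, config, params, rng)
    return new


@dataclass
class Trajectory:
    """Per-round record of a run.

    ``sizes[t]`` is the matching size at the beginning of round ``t``
    (``sizes[0]`` is the initial state); the event counters describe the
    round that led from state ``t`` to ``t+1``.
    """

    sizes: list[int] = field(default_factory=list)
    unmatched: list[int] = field(default_factory=list)
    proposals: list[int] = field(default_factory=list)
    acceptances: list[int] = field(default_factory=list)
    switches: list[int] = field(default_factory=list)
    status: str = "max_rounds"  # "reached_target" | "max_rounds"
    target_size: Optional[int] = None
    max_size: Optional[int] = None
    final_config: Optional[Configuration] = None

    @property
    def rounds(self) -> int:
        """Number of executed rounds."""
        return len(self.sizes) - 1

    @property
    def final_size(self) -> int:
        return self.sizes[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "round": range(len(self.sizes)),
                "size": self.sizes,
                "unmatched": self.unmatched,
                "proposals": self.proposals + [0],
                "acceptances": self.acceptances + [0],
                "switches": self.switches + [0],
            }
        )


def _resolve_target(G: nx.Graph, stop, max_size: Optional[int]) -> tuple[Optional[int], int]:
    """Map a stop criterion to a size target; returns (target, max_size)."""
    n = G.number_of_nodes()
    if max_size is None:
        max_size = maximum_matching_size(G)
    if stop == "perfect":
        if 2 * max_size != n:
            raise ValueError("stop='perfect' is infeasible: the graph has no perfect matching")
        return max_size, max_size
    if stop == "maximum":
        return max_size, max_size
    if stop == "rounds":
        return None, max_size
    if isinstance(stop, tuple) and len(stop) == 2 and stop[0] == "size":
        s = int(stop[1])
        if s > max_size:
            raise ValueError(f"stop target size {s} exceeds the maximum matching size {max_size}")
        return s, max_size
    raise ValueError(f"unknown stop criterion: {stop!r}")


def run(
    G: nx.Graph,
    init: Optional[Iterable] = None,
    params: EngineParams = EngineParams(),
    stop="maximum",
    *,
    max_size: Optional[int] = None,
    record_events: bool = True,
) -> Trajectory:
    """Run the prudence dynamics until ``stop`` or ``params.max_rounds``.

    ``init`` is an initial matching (or ``None`` for the empty one);
    ``stop`` is ``"perfect"``, ``"maximum"``, ``("size", s)`` or
    ``"rounds"``.  ``max_size`` may be supplied when the maximum matching
    size of ``G`` is already known (it is checked against the stop
    target, not recomputed).  The trajectory is fully determined by
    ``(G, init, params)``.
    """
    target, max_size = _resolve_target(G, stop, max_size)
    adj = _adjacency(G)
    pref = init if isinstance(init, dict) else init_configuration(G, init)
    rng = Random(params.seed)
    n = len(adj)
    pure = params.nonprudent_prob == 0.0

    traj = Trajectory(target_size=target, max_size=max_size)
    size = len(matching_of(pref))
    traj.sizes.append(size)
    traj.unmatched.append(n - 2 * size)
    while True:
        if target is not None and size >= target:
            traj.status = "reached_target"
            break
        if traj.rounds >= params.max_rounds:
            traj.status = "max_rounds"
            break
        pref, counts = _step(adj, pref, params, rng)
        new_size = len(matching_of(pref))
        if pure and new_size < size:
            raise PrudenceViolation(
                f"matching size decreased {size} -> {new_size} under pure prudence"
            )
        size = new_size
        traj.sizes.append(size)
        traj.unmatched.append(n - 2 * size)
        if record_events:
            traj.proposals.append(counts[0])
            traj.acceptances.append(counts[1])
            traj.switches.append(counts[2])
    traj.final_config = pref
    return traj


def rounds_to_ratio(traj: Trajectory, G: nx.Graph, ratio) -> Optional[int]:
    """First round at which the matching size reaches ``ceil(ratio * m*)``,
    where ``m*`` is the maximum matching size; ``None`` if never reached."""
    r = Fraction(ratio).limit_denominator(10**6) if not isinstance(ratio, Fraction) else ratio
    if not 0 < r <= 1:
        raise ValueError(f"ratio must lie in (0, 1], got {ratio}")
    m = traj.max_size if traj.max_size is not None else maximum_matching_size(G)
    target = math.ceil(r * m)
    for t, s in enumerate(traj.sizes):
        if s >= target:
            return t
    return None
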