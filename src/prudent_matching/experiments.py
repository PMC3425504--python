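"""Preset experiment suites for the prudence matching dynamics.

The harness runs seeded batches of the engine over the graph families and
aggregates rounds-to-milestone statistics:

* :func:`run_experiment` — the generic (family x size x graph x run) grid,
  returning a tidy per-run table.
* :func:`ring_scaling_report` — growth class of the rounds needed to reach
  a 1/2-approximate matching on rings (expected logarithmic for
  bounded-degree graphs).
* :func:`bad_graph_scaling_report` — growth of the rounds needed to reach
  the unique perfect matching of the bad graph when starting from
  near-perfect matchings with one free node per side (expected geometric).
* :func:`bad_matching_fraction` — exact fraction of near-perfect matchings
  of the bad graph that are of that slow kind.
* :func:`topology_comparison` — small-world vs preferential-attachment vs
  bad graph at a common size, with bootstrap confidence intervals.

Every run's seed is derived deterministically from the master seed and the
run's coordinates, so any table is exactly reproducible (and resumable)
from its spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from random import Random
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import graphs as gg
from . import matching as mc
from .engine import EngineParams, run, rounds_to_ratio

__all__ = [
    "ExperimentSpec",
    "run_experiment",
    "aggregate",
    "sample_bad_matching",
    "ring_scaling_report",
    "bad_graph_scaling_report",
    "bad_matching_fraction",
    "topology_comparison",
]

FAMILIES = ("badgraph", "ring", "smallworld", "pa", "random-pm")

#: Default milestone ratios; at 24 nodes these are matching sizes 6, 10, 11, 12.
DEFAULT_MILESTONES = (Fraction(1, 2), Fraction(5, 6), Fraction(11, 12), Fraction(1))


def derive_seed(master: int, *key: int) -> int:
    """Deterministic per-run seed below 2**31 from the master seed and coordinates."""
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ExperimentSpec:
    """A (family x sizes x graphs x runs) batch of engine runs.

    ``sizes`` are node counts.  ``init`` is ``"empty"`` or ``"bad"`` (the
    latter only for the bad-graph family: a uniformly sampled near-perfect
    matching with one free node per side).  The full-scale protocol
    (100 graphs x 1000 runs) is obtained by setting ``graphs_per_size``
    and ``runs_per_graph`` accordingly; defaults are desk-scale.
    """

    family: str
    sizes: tuple[int, ...]
    graphs_per_size: int = 20
    runs_per_graph: int = 100
    keep_prob: float = 0.2
    nonprudent_prob: float = 0.0
    max_rounds: int = 10_000
    stop: str = "maximum"
    milestones: tuple = DEFAULT_MILESTONES
    init: str = "empty"
    master_seed: int = 0
    family_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.graphs_per_size < 1 or self.runs_per_graph < 1:
            raise ValueError("graphs_per_size and runs_per_graph must be positive")
        if self.init not in ("empty", "bad"):
            raise ValueError(f"init must be 'empty' or 'bad', got {self.init!r}")
        if self.init == "bad" and self.family != "badgraph":
            raise ValueError("init='bad' is only defined for the badgraph family")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown experiment spec keys: {sorted(unknown)}")
        d = dict(d)
        if "sizes" in d:
            d["sizes"] = tuple(d["sizes"])
        if "milestones" in d:
            d["milestones"] = tuple(Fraction(x).limit_denominator(10**6) for x in d["milestones"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sizes"] = list(self.sizes)
        d["milestones"] = [float(m) for m in self.milestones]
        return d


def make_family_graph(family: str, size: int, seed: int, params: Optional[dict] = None) -> nx.Graph:
    """Instantiate one graph of ``family`` with ``size`` nodes."""
    params = params or {}
    if family == "badgraph":
        if size % 2:
            raise ValueError("badgraph size (node count) must be even")
        return gg.make_bad_graph(size // 2)
    if family == "ring":
        return gg.make_ring(size)
    if family == "smallworld":
        return gg.make_small_world(size, k=params.get("k", 4), p=params.get("p", 0.1), seed=seed)
    if family == "pa":
        return gg.make_preferential_attachment(size, m=params.get("m", 2), seed=seed)
    if family == "random-pm":
        return gg.make_random_pm_graph(
            size,
            bipartite=params.get("bipartite", True),
            multiplicity=params.get("multiplicity", "unique"),
            extra_edges=params.get("extra_edges", 4),
            seed=seed,
        )
    raise ValueError(f"unknown family {family!r}")


def sample_bad_matching(n: int, rng: Random) -> frozenset:
    """A near-perfect matching of the bad graph with one free node per side.

    For ``n <= 7`` sampled uniformly from the exhaustively enumerated
    family; for larger ``n`` drawn from the constructive "shifted
    horizontal" family: a pivot ``p`` is chosen uniformly and the
    horizontal edges below it are shifted down by one, leaving ``a_1`` and
    ``b_p`` free.
    """
    if n <= 7:
        fam = mc.bad_matchings(n)
        return fam[rng.randrange(len(fam))]
    p = rng.randrange(1, n + 1)
    edges = [(f"a{i}", f"b{i}") for i in range(p + 1, n + 1)]
    edges += [(f"a{i}", f"b{i - 1}") for i in range(2, p + 1)]
    return mc.normalize_matching(edges)


def run_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Execute the batch and return one row per (size, graph, run).

    Columns: family, n, graph_id, run_id, seed, status, rounds,
    final_size, max_size, and ``rounds_to_<r>`` per milestone (NaN when
    the run was censored before reaching it).  Graphs whose stop target is
    infeasible yield a flagged ``status='infeasible'`` row instead of
    being dropped.
    """
    rows = []
    for si, size in enumerate(spec.sizes):
        for g in range(spec.graphs_per_size):
            gseed = derive_seed(spec.master_seed, 1, si, g)
            G = make_family_graph(spec.family, size, gseed, spec.family_params)
            max_size = mc.maximum_matching_size(G)
            for r in range(spec.runs_per_graph):
                rseed = derive_seed(spec.master_seed, 2, si, g, r)
                params = EngineParams(
                    keep_prob=spec.keep_prob,
                    nonprudent_prob=spec.nonprudent_prob,
                    seed=rseed,
                    max_rounds=spec.max_rounds,
                )
                init = None
                if spec.init == "bad":
                    init = sample_bad_matching(size // 2, Random(derive_seed(spec.master_seed, 3, si, g, r)))
                row = {
                    "family": spec.family, "n": size, "graph_id": g, "run_id": r,
                    "seed": rseed,
                }
                try:
                    traj = run(G, init, params, stop=spec.stop, max_size=max_size)
                except ValueError as exc:
                    row.update(status=f"infeasible: {exc}", rounds=np.nan,
                               final_size=np.nan, max_size=max_size)
                    rows.append(row)
                    continue
                row.update(
                    status=traj.status, rounds=traj.rounds,
                    final_size=traj.final_size, max_size=max_size,
                )
                for m in spec.milestones:
                    t = rounds_to_ratio(traj, G, m)
                    row[f"rounds_to_{float(m):g}"] = np.nan if t is None else t
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate(df: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd/count of rounds (and milestones) per (family, n); censored
    runs enter at the cap, and their count is reported explicitly."""
    value_cols = ["rounds"] + [c for c in df.columns if c.startswith("rounds_to_")]
    out = df.groupby(["family", "n"]).agg(
        runs=("rounds", "size"),
        censored=("status", lambda s: int((s == "max_rounds").sum())),
        **{f"mean_{c}": (c, "mean") for c in value_cols},
        **{f"sd_{c}": (c, "std") for c in value_cols},
    )
    return out.reset_index()


def _fit_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R-squared of an ordinary least-squares line y ~ a + b x."""
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def ring_scaling_report(
    sizes: Sequence[int] = (8, 16, 32, 64, 128),
    reps: int = 500,
    ratio=Fraction(1, 2),
    keep_prob: float = 0.2,
    max_rounds: int = 10_000,
    master_seed: int = 0,
) -> dict:
    """Growth class of mean rounds to a ``ratio``-approximate matching on rings.

    Fits the per-size means against ``log n`` and against ``n`` and
    reports both R-squared values; the verdict is ``"sublinear"`` when the
    logarithmic model explains the data at least as well as the linear one
    (a constant sequence is flagged degenerate and counts as sublinear).
    """
    if len(sizes) < 4:
        raise ValueError("need at least 4 sizes to classify the growth")
    means = {}
    for si, n in enumerate(sorted(sizes)):
        G = gg.make_ring(n)
        max_size = n // 2
        vals = []
        for r in range(reps):
            params = EngineParams(
                keep_prob=keep_prob, seed=derive_seed(master_seed, 10, si, r), max_rounds=max_rounds
            )
            traj = run(G, None, params, stop=("size", math.ceil(ratio * max_size)), max_size=max_size)
            t = rounds_to_ratio(traj, G, ratio)
            vals.append(traj.rounds if t is None else t)
        means[n] = float(np.mean(vals))
    ns = np.array(sorted(means))
    ys = np.array([means[n] for n in ns], dtype=float)
    degenerate = bool(np.allclose(ys, ys[0]))
    r2_log = _fit_r2(np.log(ns), ys)
    r2_lin = _fit_r2(ns.astype(float), ys)
    verdict = "sublinear" if degenerate or r2_log >= r2_lin else "not-sublinear"
    return {
        "sizes": [int(n) for n in ns],
        "mean_rounds": {int(n): means[n] for n in ns},
        "ratio": float(ratio),
        "reps": reps,
        "r2_log": r2_log,
        "r2_linear": r2_lin,
        "degenerate": degenerate,
        "verdict": verdict,
    }


def bad_graph_scaling_report(
    grid: Sequence[int] = (3, 4, 5, 6),
    reps: int = 200,
    keep_prob: float = 0.2,
    cap: int = 10_000,
    master_seed: int = 0,
) -> dict:
    """Mean rounds to the perfect matching of the bad graph from slow starts.

    For each side size ``n`` in ``grid``, ``reps`` runs start from a
    uniformly sampled near-perfect matching with one free node per side.
    Runs censored at ``cap`` enter the mean at the cap (a lower bound) and
    are counted.  Successive means are compared: geometric growth is
    declared when every ratio ``mean(n+1)/mean(n)`` exceeds 1.
    """
    per_n = {}
    for ni, n in enumerate(sorted(grid)):
        if n < 2:
            raise ValueError("grid sizes must be >= 2 (side size 1 is a single edge)")
        G = gg.make_bad_graph(n)
        vals, censored = [], 0
        for r in range(reps):
            rng = Random(derive_seed(master_seed, 20, ni, r))
            init = sample_bad_matching(n, rng)
            params = EngineParams(
                keep_prob=keep_prob, seed=derive_seed(master_seed, 21, ni, r), max_rounds=cap
            )
            traj = run(G, init, params, stop="perfect", max_size=n)
            if traj.status == "max_rounds":
                censored += 1
                vals.append(cap)
            else:
                vals.append(traj.rounds)
        per_n[n] = {"mean_rounds": float(np.mean(vals)), "censored": censored, "reps": reps}
    ns = sorted(per_n)
    ratios = [per_n[b]["mean_rounds"] / per_n[a]["mean_rounds"] for a, b in zip(ns, ns[1:])]
    return {
        "grid": ns,
        "per_n": per_n,
        "ratios": ratios,
        "cap": cap,
        "geometric": bool(all(r > 1.0 for r in ratios)),
    }


def bad_matching_fraction(n: int, strict: bool = False) -> Fraction:
    """Exact fraction of (n-1)-matchings of the bad graph whose two free
    nodes lie on opposite sides (the slow starting states).

    In a balanced bipartite graph every (n-1)-matching leaves exactly one
    free node per side, so the default (opposite-side) fraction is
    identically 1.  With ``strict=True`` the numerator is restricted to
    matchings whose free pair is *non-adjacent* — the starts that cannot be
    completed in a single augmentation; this fraction is (2^n - n - 1) /
    (2^n - 1), strictly increasing towards 1 ("almost all near-perfect
    matchings are slow").
    """
    G = gg.make_bad_graph(n)
    fam = mc.enumerate_matchings(G, n - 1)
    if not strict:
        return Fraction(len(mc.bad_matchings(n)), len(fam))
    count = 0
    for M in fam:
        free = sorted(set(G) - mc.matched_nodes(M))
        a = next(x for x in free if x[0] == "a")
        b = next(x for x in free if x[0] == "b")
        count += not G.has_edge(a, b)
    return Fraction(count, len(fam))


def _bootstrap_ci(values_by_graph: list[np.ndarray], rng: np.random.Generator,
                  n_boot: int = 1000, level: float = 0.95) -> tuple[float, float]:
    """Percentile CI of the grand mean, resampling graphs (the experiment's
    top-level unit) with replacement."""
    means = np.array([v.mean() for v in values_by_graph])
    boots = np.empty(n_boot)
    k = len(means)
    for i in range(n_boot):
        boots[i] = means[rng.integers(0, k, size=k)].mean()
    lo, hi = np.quantile(boots, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def topology_comparison(
    n: int = 24,
    graphs_per_family: int = 20,
    runs_per_graph: int = 100,
    keep_prob: float = 0.2,
    cap: int = 2000,
    families: Sequence[str] = ("smallworld", "pa", "badgraph"),
    family_params: Optional[dict] = None,
    master_seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Compare mean rounds-to-maximum across network families at size ``n``.

    Censored runs enter the mean at ``cap``.  Bootstrap CIs resample the
    per-graph means.  The ordering verdict is the family sequence sorted
    by mean, qualified as ``"inconclusive"`` when adjacent CIs overlap.
    The bad graph is a single deterministic instance per size; its
    ``graphs_per_family`` copies differ only in run seeds.
    """
    family_params = family_params or {}
    report: dict = {"n": n, "cap": cap, "families": {}}
    boot_rng = np.random.default_rng(derive_seed(master_seed, 30))
    for fi, fam in enumerate(families):
        by_graph, half_rounds, censored = [], [], 0
        for g in range(graphs_per_family):
            G = make_family_graph(fam, n, derive_seed(master_seed, 31, fi, g),
                                  family_params.get(fam))
            max_size = mc.maximum_matching_size(G)
            vals = []
            for r in range(runs_per_graph):
                params = EngineParams(
                    keep_prob=keep_prob, seed=derive_seed(master_seed, 32, fi, g, r),
                    max_rounds=cap,
                )
                traj = run(G, None, params, stop=("size", max_size), max_size=max_size)
                if traj.status == "max_rounds":
                    censored += 1
                    vals.append(cap)
                else:
                    vals.append(traj.rounds)
                t_half = rounds_to_ratio(traj, G, Fraction(1, 2))
                half_rounds.append(cap if t_half is None else t_half)
            by_graph.append(np.array(vals, dtype=float))
        lo, hi = _bootstrap_ci(by_graph, boot_rng, n_boot=n_boot)
        allvals = np.concatenate(by_graph)
        report["families"][fam] = {
            "mean_rounds": float(allvals.mean()),
            "ci": (lo, hi),
            "censored": censored,
            "runs": int(allvals.size),
            "median_rounds_to_half": float(np.median(half_rounds)),
        }
    order = sorted(report["families"], key=lambda f: report["families"][f]["mean_rounds"])
    conclusive = all(
        report["families"][a]["ci"][1] < report["families"][b]["ci"][0]
        for a, b in zip(order, order[1:])
    )
    report["ordering"] = order
    report["verdict"] = " < ".join(order) if conclusive else "inconclusive"
    return report
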