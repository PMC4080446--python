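"""Permutation null models for subnetwork topology.

Two nulls are provided. The *global* null re-draws seed gene sets of the
observed size uniformly from the parent weighted network and rebuilds the
seed subnetwork each time, asking whether the observed subnetwork's size and
topology could arise from arbitrary seeds. The *local* null preserves the
degree sequence of a network (typically a giant component) exactly, using
repeated double-edge swaps, and asks whether clustering/betweenness exceed
what the degree sequence alone implies.

Empirical p-values use the add-one rule p = (1 + #{v beyond observed}) /
(B + 1), so p is never zero and is bounded below by 1/(B+1).
"""

from __future__ import annotations

import logging
import math
import warnings

import networkx as nx
import numpy as np

from .network import extract_seed_subnetwork, topology_summary
from .types import NullDistribution, TopologySummary

logger = logging.getLogger(__name__)

GLOBAL_STATS = ("n_nodes", "n_edges", "mean_degree", "mean_clustering",
                "mean_betweenness")
LOCAL_STATS = ("mean_clustering", "mean_betweenness")


def empirical_p(observed: float, values, tail: str = "ge") -> float:
    """Add-one empirical p-value against permutation replicates."""
    values = np.asarray(values, float)
    if tail == "ge":
        extreme = int(np.sum(values >= observed))
    elif tail == "le":
        extreme = int(np.sum(values <= observed))
    else:
        raise ValueError("tail must be 'ge' or 'le'")
    return (1 + extreme) / (len(values) + 1)


def _null_from_values(statistic, observed, values) -> NullDistribution:
    """Choose the tail by where the observed value sits relative to the null
    mean, and report it alongside the one-sided p."""
    values = np.asarray(values, float)
    finite = values[np.isfinite(values)]
    tail = "ge" if observed >= (finite.mean() if finite.size else 0.0) else "le"
    return NullDistribution(
        statistic=statistic,
        observed=float(observed),
        values=values,
        tail=tail,
        p=empirical_p(observed, finite, tail),
    )


def global_null(
    net: nx.Graph,
    seed_size: int,
    B: int = 1000,
    rng_seed: int = 0,
    observed: TopologySummary | None = None,
    mode: str = "seed",
    statistics: tuple[str, ...] = GLOBAL_STATS,
) -> dict[str, NullDistribution]:
    """Random-seed null: B replicate subnetworks of ``net``.

    Each replicate samples ``seed_size`` nodes uniformly without
    replacement. With ``mode="seed"`` the seed subnetwork (seeds plus first
    neighbours) is extracted; with ``mode="induced"`` the induced subgraph
    on the sampled set alone is taken — the construction used for the
    chromatin-side subnetwork. Returns a NullDistribution per statistic
    (requires ``observed``; without it the raw replicate tables are
    returned under the same keys with NaN p).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("seed", "induced"):
        raise ValueError("mode must be 'seed' or 'induced'")
    nodes = sorted(net.nodes())
    if seed_size > len(nodes):
        raise ValueError("seed_size exceeds node count")
    unknown = set(statistics) - set(GLOBAL_STATS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    sizes_only = set(statistics) <= {"n_nodes", "n_edges", "mean_degree"}
    rng = np.random.default_rng(rng_seed)
    reps: dict[str, list[float]] = {s: [] for s in statistics}
    for _ in range(B):
        seeds = set(rng.choice(nodes, size=seed_size, replace=False))
        if mode == "seed":
            sub = extract_seed_subnetwork(net, seeds)
        else:
            sub = net.subgraph(seeds)
        if sub.number_of_nodes() == 0:
            summ = TopologySummary(0, 0, 0.0, 0.0, 0.0, float("nan"))
        elif sizes_only:
            n, m = sub.number_of_nodes(), sub.number_of_edges()
            summ = TopologySummary(n, m, 2.0 * m / n, float("nan"),
                                   float("nan"), float("nan"))
        else:
            summ = topology_summary(sub)
        for s in statistics:
            reps[s].append(getattr(summ, s))
    out = {}
    for s in statistics:
        obs = getattr(observed, s) if observed is not None else float("nan")
        out[s] = _null_from_values(s, obs, reps[s])
    return out


def degree_preserving_rewire(
    net: nx.Graph,
    swap_fraction: float = 0.5,
    rng_seed: int = 0,
    max_attempts: int | None = None,
) -> nx.Graph:
    """Randomize a network by double-edge swaps, preserving every degree.

    A proposal picks two edges (a,b), (c,d) with four distinct endpoints and
    replaces them with (a,d), (c,b) when neither replacement already exists.
    Accepted swaps continue until ceil(swap_fraction x |E|) succeed;
    rejected proposals do not count. If no valid swap is found within
    ``max_attempts`` proposals (default 100·|E|), the graph achieved so far
    is returned with a warning. Edge weights are dropped: the null is purely
    topological. The achieved swap count is stored in
    ``graph.graph["n_swaps"]``.
    """
    if net.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = np.random.default_rng(rng_seed)
    edges = [tuple(e) for e in net.edges()]
    edge_set = {frozenset(e) for e in edges}
    n_edges = len(edges)
    target = math.ceil(swap_fraction * n_edges)
    if max_attempts is None:
        max_attempts = 100 * n_edges

    swaps = attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # random orientation of each picked edge
        if rng.integers(0, 2):
            a, b = b, a
        if rng.integers(0, 2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swaps += 1
    if swaps < target:
        warnings.warn(
            f"degree_preserving_rewire: achieved {swaps}/{target} swaps "
            f"after {attempts} attempts",
            RuntimeWarning,
            stacklevel=2,
        )
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(edges)
    out.graph["n_swaps"] = swaps
    return out


def local_null(
    component: nx.Graph,
    B: int = 1000,
    swap_fraction: float = 0.5,
    rng_seed: int = 0,
    observed: TopologySummary | None = None,
) -> dict[str, NullDistribution]:
    """Degree-preserving rewiring null for a connected component.

    B rewired replicates; mean clustering coefficient and mean betweenness
    are summarized per replicate.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng_seed)
    reps: dict[str, list[float]] = {s: [] for s in LOCAL_STATS}
    for _ in range(B):
        rep = degree_preserving_rewire(
            component, swap_fraction, rng_seed=int(rng.integers(0, 2**31 - 1))
        )
        summ = topology_summary(rep)
        for s in LOCAL_STATS:
            reps[s].append(getattr(summ, s))
    out = {}
    for s in LOCAL_STATS:
        obs = getattr(observed, s) if observed is not None else float("nan")
        out[s] = _null_from_values(s, obs, reps[s])
    return out
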