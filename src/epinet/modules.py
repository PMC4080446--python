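"""Dense-module detection and the module-overlap interplay test.

Module mining follows the MCODE scheme: each node is weighted by the
k-core number of the highest k-core of its closed neighbourhood times that
core's edge density, and modules grow greedily from the highest-weight
unvisited seed, admitting unvisited neighbours whose weight is at least
(1 − node_score_cutoff) x the seed weight. An optional haircut removes
singly-connected module vertices; modules smaller than ``min_size`` are
dropped. Modules are vertex-disjoint (a node joins at most one module).

The interplay test asks, for a methylation module of size M and a chromatin
module of size H over a background of N genes, whether their overlap x is
larger than hypergeometric chance:

    P(X >= x) = 1 − Σ_{k=0}^{x−1} C(M,k) C(N−M,H−k) / C(N,H)

computed exactly in log space. Pairs with overlap >= min_overlap are the
tested candidates and define the Bonferroni factor.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp

from .types import InterplayResult, Module, ModuleSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- hypergeometric


def _log_comb(n, k) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(N: int, M: int, H: int, x: int) -> float:
    """Exact upper-tail P(X >= x) for X ~ Hypergeometric(N, M, H).

    N: background size; M: genes in the first set; H: draws (genes in the
    second set); x: observed overlap.
    """
    if not (0 <= M <= N and 0 <= H <= N):
        raise ValueError(f"infeasible sizes N={N}, M={M}, H={H}")
    if not (0 <= x <= min(M, H)):
        raise ValueError(f"infeasible overlap x={x} for M={M}, H={H}")
    if x == 0:
        return 1.0
    k_lo = max(x, M + H - N)
    k_hi = min(M, H)
    if k_lo > k_hi:
        return 0.0
    ks = np.arange(k_lo, k_hi + 1)
    log_terms = (
        _log_comb(M, ks) + _log_comb(N - M, H - ks) - _log_comb(N, H)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


# ---------------------------------------------------------------- MCODE


def mcode_weights(net: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """Core-density vertex weights.

    weight(v) = k_max x density of the k_max-core of v's closed
    neighbourhood, where k_max is the largest k with a non-empty k-core.
    Isolated vertices score 0; vertices with degree < degree_cutoff score 0
    (they cannot anchor a dense region).
    """
    weights: dict[str, float] = {}
    for v in net:
        nbrs = set(net.neighbors(v))
        if len(nbrs) < 1 or net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        closed = net.subgraph(nbrs | {v})
        core_num = nx.core_number(closed)
        k_max = max(core_num.values())
        core_nodes = [u for u, k in core_num.items() if k >= k_max]
        core = closed.subgraph(core_nodes)
        n = core.number_of_nodes()
        density = 2 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        weights[v] = k_max * density
    return weights


def _haircut(net: nx.Graph, members: set[str]) -> set[str]:
    """Drop module vertices with < 2 module-internal edges (single pass)."""
    sub = net.subgraph(members)
    drop = {v for v in members if sub.degree(v) < 2}
    if drop == set(members):
        return set(members)
    return set(members) - drop


def mcode_modules(
    net: nx.Graph,
    node_score_cutoff: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_size: int = 3,
    degree_cutoff: int = 2,
    source: str = "",
) -> ModuleSet:
    """Greedy dense-module detection.

    Deterministic given the tie-break: seeds in descending weight then
    ascending node id; expansion is breadth-first over unvisited neighbours
    with weight >= (1 − node_score_cutoff) x seed weight. ``fluff`` is
    accepted for interface completeness but not implemented (off by
    default, as in typical use).
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not supported")
    if net.number_of_nodes() == 0:
        return ModuleSet([], source=source)
    weights = mcode_weights(net, degree_cutoff=degree_cutoff)
    order = sorted(net.nodes(), key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    modules: list[Module] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            v = frontier.pop(0)
            for u in net.neighbors(v):
                if u in visited:
                    continue
                if weights[u] >= threshold:
                    visited.add(u)
                    members.add(u)
                    frontier.append(u)
        if haircut:
            members = _haircut(net, members)
        if len(members) >= min_size:
            sub = net.subgraph(members)
            n = len(members)
            density = 2 * sub.number_of_edges() / (n * (n - 1))
            score = density * n  # MCODE module score: density x size
            modules.append(Module(f"M{len(modules) + 1}", frozenset(members), score))
    modules.sort(key=lambda m: (-m.score, m.module_id))
    modules = [
        Module(f"M{i + 1}", m.genes, m.score) for i, m in enumerate(modules)
    ]
    return ModuleSet(modules, source=source)


# ---------------------------------------------------------------- interplay


def interplay(
    meth: ModuleSet,
    chrom: ModuleSet,
    background: set[str],
    min_overlap: int = 3,
    alpha: float = 0.05,
    N: int | None = None,
) -> list[InterplayResult]:
    """Cross every methylation module with every chromatin module.

    ``background`` is the gene universe, by default the union of the two
    subnetworks' gene sets; pass ``N`` to use a different background size
    (e.g. the sum of the two subnetworks' node counts) while still
    validating module membership against ``background``. Pairs with overlap
    >= ``min_overlap`` are tested; the Bonferroni factor is the number of
    tested candidates. All pairs are reported, untested ones with NaN
    corrected p.
    """
    all_genes = set().union(*(m.genes for m in meth), set()) | set().union(
        *(m.genes for m in chrom), set()
    )
    if not all_genes <= set(background):
        raise ValueError("background must contain every module gene")
    if N is None:
        N = len(background)
    elif N < len(background):
        raise ValueError("N smaller than the validated background")
    results: list[InterplayResult] = []
    candidates: list[int] = []
    for mm in meth:
        for cm in chrom:
            overlap = mm.genes & cm.genes
            x = len(overlap)
            p_raw = hypergeom_upper(N, mm.size, cm.size, x)
            tested = x >= min_overlap
            results.append(
                InterplayResult(
                    meth_module=mm.module_id,
                    chrom_module=cm.module_id,
                    background_size=N,
                    meth_size=mm.size,
                    chrom_size=cm.size,
                    overlap_size=x,
                    overlap_genes=frozenset(overlap),
                    p_raw=p_raw,
                    p_bonferroni=float("nan"),
                    tested=tested,
                    significant=False,
                )
            )
            if tested:
                candidates.append(len(results) - 1)
    factor = len(candidates)
    for idx in candidates:
        r = results[idx]
        r.p_bonferroni = min(1.0, r.p_raw * factor)
        r.significant = r.p_bonferroni < alpha
    return results
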