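"""Weighted epigenetic network construction and topology summaries.

A weighted network keeps a background interaction only when the two genes'
profiles (per-sample methylation betas, or the per-mark chromatin intensity
vector) are strongly correlated: |Pearson r| > r_cut and two-sided p < alpha
with p from the t approximation t = r·sqrt(df / (1 − r²)), df = n − 2.

Seed subnetworks take a set of seed genes plus their first neighbours and
the induced edges — the construction used for the disease-related
methylation subnetwork (seeds = differentially methylated genes in the
weighted methylation network) and, on the chromatin side, the induced
subgraph of the weighted chromatin network on that subnetwork's gene set.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import InteractionSet, TopologySummary

logger = logging.getLogger(__name__)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t approximation."""
    df = n - 2
    if df <= 0:
        return 1.0
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def weight_network(
    interactions: InteractionSet,
    profiles: pd.DataFrame,
    r_cut: float = 0.8,
    alpha: float = 0.05,
) -> nx.Graph:
    """Filter background edges by profile correlation.

    ``profiles`` is a gene x observation DataFrame (columns: samples or
    marks). An edge is kept iff both endpoints have profiles, |r| > r_cut
    (strict) and p < alpha (strict). Kept edges carry ``r`` and ``p``.
    Genes without a profile are dropped from the node set; genes with a
    profile stay as nodes even if all their edges are pruned. Zero-variance
    profiles cannot be correlated; such edges are skipped and logged.
    """
    n_obs = profiles.shape[1]
    if n_obs < 3:
        raise ValueError("profiles need at least 3 observations")
    values = profiles.to_numpy(float)
    index = {g: i for i, g in enumerate(profiles.index)}
    sd = values.std(axis=1)
    centered = values - values.mean(axis=1, keepdims=True)
    # unit-norm rows where defined, so r = dot product
    norm = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm[:, None] > 0, centered / np.where(norm == 0, 1, norm)[:, None], 0.0)

    net = nx.Graph()
    net.add_nodes_from(g for g in profiles.index if g in _interaction_genes(interactions))
    n_zero_var = 0
    for a, b in interactions:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            continue
        if sd[ia] == 0 or sd[ib] == 0:
            n_zero_var += 1
            continue
        r = float(np.clip(unit[ia] @ unit[ib], -1.0, 1.0))
        if abs(r) <= r_cut:
            continue
        p = correlation_pvalue(r, n_obs)
        if p >= alpha:
            continue
        net.add_edge(a, b, r=r, p=p)
    if n_zero_var:
        logger.info("weight_network: skipped %d edges with a zero-variance profile",
                    n_zero_var)
    return net


def _interaction_genes(interactions: InteractionSet) -> frozenset[str]:
    return interactions.genes


def extract_seed_subnetwork(net: nx.Graph, seeds: set[str]) -> nx.Graph:
    """Seeds plus first neighbours, with all induced edges.

    Seeds absent from the network are ignored (logged). Nodes carry a
    boolean ``seed`` attribute.
    """
    present = {s for s in seeds if s in net}
    missing = len(seeds) - len(present)
    if missing:
        logger.info("extract_seed_subnetwork: %d seeds absent from network", missing)
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    sub = net.subgraph(nodes).copy()
    nx.set_node_attributes(sub, {v: (v in present) for v in sub}, "seed")
    return sub


def giant_component(net: nx.Graph) -> nx.Graph:
    """Largest connected component; ties by edge count, then smallest node id."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no giant component")
    comps = sorted(
        nx.connected_components(net),
        key=lambda c: (-len(c), -net.subgraph(c).number_of_edges(), min(c)),
    )
    return net.subgraph(comps[0]).copy()


def fit_powerlaw_exponent(degrees) -> float:
    """Negative slope of the least-squares line of log10 count vs log10 degree.

    Fitted over degrees >= 1 with nonzero histogram counts; NaN when fewer
    than two distinct such degrees exist.
    """
    degrees = np.asarray(list(degrees))
    degrees = degrees[degrees >= 1]
    if degrees.size == 0:
        return float("nan")
    ks, counts = np.unique(degrees, return_counts=True)
    if len(ks) < 2:
        return float("nan")
    slope, _ = np.polyfit(np.log10(ks), np.log10(counts), 1)
    return float(-slope)


def topology_summary(net: nx.Graph) -> TopologySummary:
    """Mean degree, clustering coefficient, raw betweenness and degree-
    distribution exponent.

    Clustering is the local coefficient 2·T(v)/(k_v (k_v − 1)) (0 when
    k_v < 2); betweenness is unweighted shortest-path betweenness,
    non-normalized.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    degrees = [d for _, d in net.degree()]
    mean_degree = float(np.mean(degrees))
    mean_cc = float(np.mean(list(nx.clustering(net).values())))
    betw = nx.betweenness_centrality(net, normalized=False)
    mean_betw = float(np.mean(list(betw.values())))
    return TopologySummary(
        n_nodes=n,
        n_edges=net.number_of_edges(),
        mean_degree=mean_degree,
        mean_clustering=mean_cc,
        mean_betweenness=mean_betw,
        powerlaw_exponent=fit_powerlaw_exponent(degrees),
    )
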