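"""Correlation-filtered network construction, seed subnetworks and
topology, checked against closed forms and exhaustive path enumeration."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epinet import (extract_seed_subnetwork, fit_powerlaw_exponent,
                    giant_component, topology_summary, weight_network)
from epinet.network import correlation_pvalue
from epinet.types import InteractionSet


def profiles_with_correlation(r, n=5):
    """Two profiles of length n with Pearson correlation exactly r."""
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    xu = xc / np.linalg.norm(xc)
    e = np.random.default_rng(0).normal(size=n)
    e -= e.mean()
    e -= (e @ xu) * xu  # orthogonal to x, mean zero
    eu = e / np.linalg.norm(e)
    y = r * xu + np.sqrt(1 - r**2) * eu
    return x, y


class TestWeightNetwork:
    def test_identical_profiles_kept_with_r_one(self):
        inter = InteractionSet.from_pairs([("a", "b")])
        prof = pd.DataFrame(
            [[0.1, 0.5, 0.9, 0.2, 0.7]] * 2, index=["a", "b"]
        )
        net = weight_network(inter, prof)
        assert net.has_edge("a", "b")
        assert net["a"]["b"]["r"] == pytest.approx(1.0)

    def test_moderate_correlation_pruned_regardless_of_p(self):
        # r = 0.5 over 100 samples is highly significant but fails |r| > 0.8
        x, y = profiles_with_correlation(0.5, n=100)
        assert correlation_pvalue(0.5, 100) < 1e-6
        inter = InteractionSet.from_pairs([("a", "b")])
        prof = pd.DataFrame([x, y], index=["a", "b"])
        assert weight_network(inter, prof).number_of_edges() == 0

    def test_short_profile_high_r_pruned_by_p_filter(self):
        # |r| = 0.85 over 5 marks: passes the r filter but p(df=3) ~ 0.068
        x, y = profiles_with_correlation(0.85, n=5)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.85)
        assert correlation_pvalue(0.85, 5) == pytest.approx(0.0679, abs=1e-3)
        inter = InteractionSet.from_pairs([("a", "b")])
        net = weight_network(inter, pd.DataFrame([x, y], index=["a", "b"]))
        assert net.number_of_edges() == 0

    def test_p_value_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 16))
        r, p_ref = stats.pearsonr(x, y)
        assert correlation_pvalue(r, 16) == pytest.approx(p_ref, rel=1e-9)

    def test_zero_variance_profile_skipped(self):
        inter = InteractionSet.from_pairs([("a", "b")])
        prof = pd.DataFrame([[0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]],
                            index=["a", "b"])
        assert weight_network(inter, prof).number_of_edges() == 0

    def test_invariant_to_edge_and_endpoint_order(self):
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.normal(size=(6, 16)),
                            index=list("abcdef"))
        pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("a", "f")]
        n1 = weight_network(InteractionSet.from_pairs(pairs), prof, r_cut=0.0)
        n2 = weight_network(
            InteractionSet.from_pairs([(b, a) for a, b in pairs[::-1]]),
            prof, r_cut=0.0,
        )
        assert set(n1.edges()) == set(n2.edges())


class TestSeedSubnetwork:
    def make_path(self, *nodes):
        g = nx.Graph()
        for a, b in zip(nodes, nodes[1:]):
            g.add_edge(a, b, r=0.9, p=0.01)
        return g

    def test_empty_seeds_give_empty_network(self):
        net = self.make_path("A", "B", "C")
        assert extract_seed_subnetwork(net, set()).number_of_nodes() == 0

    def test_center_seed_captures_whole_path(self):
        net = self.make_path("A", "B", "C")
        sub = extract_seed_subnetwork(net, {"B"})
        assert set(sub.nodes()) == {"A", "B", "C"}
        assert sub.nodes["B"]["seed"] and not sub.nodes["A"]["seed"]

    def test_induced_edges_only(self):
        net = self.make_path("A", "B", "C", "D")
        sub = extract_seed_subnetwork(net, {"B"})
        assert set(sub.nodes()) == {"A", "B", "C"}
        assert set(map(frozenset, sub.edges())) == {
            frozenset({"A", "B"}), frozenset({"B", "C"})
        }

    def test_edges_carry_parent_weights(self):
        net = self.make_path("A", "B", "C")
        sub = extract_seed_subnetwork(net, {"B"})
        assert sub["A"]["B"] == net["A"]["B"]

    def test_random_graph_matches_exhaustive_edge_check(self):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        net = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        seeds = {"n0", "n5", "n7"}
        sub = extract_seed_subnetwork(net, seeds)
        expected_nodes = set(seeds) | {
            u for s in seeds for u in net.neighbors(s)
        }
        assert set(sub.nodes()) == expected_nodes
        for u, v in itertools.combinations(sorted(expected_nodes), 2):
            assert sub.has_edge(u, v) == net.has_edge(u, v)


class TestGiantComponent:
    def test_connected_network_returned_whole(self):
        g = nx.path_graph(5)
        assert set(giant_component(g).nodes()) == set(g.nodes())

    def test_largest_by_node_count(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (2, 0)])  # triangle
        g.add_edges_from(nx.complete_graph(range(10, 14)).edges())  # K4
        assert set(giant_component(g).nodes()) == {10, 11, 12, 13}

    def test_matches_flood_fill_oracle(self):
        g = nx.gnp_random_graph(40, 0.04, seed=4)
        # brute-force flood fill
        unvisited = set(g)
        comps = []
        while unvisited:
            start = next(iter(unvisited))
            stack, comp = [start], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(set(g.neighbors(v)) - comp)
            comps.append(comp)
            unvisited -= comp
        expected = max(comps, key=len)
        if sum(len(c) == len(expected) for c in comps) == 1:
            assert set(giant_component(g).nodes()) == expected

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            giant_component(nx.Graph())


class TestTopologySummary:
    def test_triangle(self):
        s = topology_summary(nx.complete_graph(3))
        assert s.mean_degree == pytest.approx(2.0)
        assert s.mean_clustering == pytest.approx(1.0)
        assert s.mean_betweenness == pytest.approx(0.0)

    def test_three_node_path(self):
        s = topology_summary(nx.path_graph(3))
        assert s.mean_clustering == pytest.approx(0.0)
        betw = nx.betweenness_centrality(nx.path_graph(3), normalized=False)
        assert betw[1] == pytest.approx(1.0)
        assert s.mean_betweenness == pytest.approx(1 / 3)

    def test_betweenness_matches_exhaustive_path_enumeration(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        # oracle: enumerate all simple paths, keep shortest ones per pair
        btw = {v: 0.0 for v in g}
        for s, t in itertools.combinations(sorted(g), 2):
            paths = list(nx.all_simple_paths(g, s, t))
            if not paths:
                continue
            shortest = min(map(len, paths))
            sps = [p for p in paths if len(p) == shortest]
            for p in sps:
                for v in p[1:-1]:
                    btw[v] += 1.0 / len(sps)
        summ = topology_summary(g)
        assert summ.mean_betweenness == pytest.approx(
            np.mean(list(btw.values()))
        )

    def test_clustering_matches_triangle_counting_oracle(self):
        g = nx.gnp_random_graph(20, 0.25, seed=6)
        ccs = []
        for v in g:
            nbrs = list(g.neighbors(v))
            k = len(nbrs)
            if k < 2:
                ccs.append(0.0)
                continue
            links = sum(
                1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
            )
            ccs.append(2 * links / (k * (k - 1)))
        assert topology_summary(g).mean_clustering == pytest.approx(np.mean(ccs))

    def test_mean_degree_identity(self):
        g = nx.gnp_random_graph(30, 0.2, seed=7)
        s = topology_summary(g)
        assert s.mean_degree == pytest.approx(2 * s.n_edges / s.n_nodes)


class TestPowerlawFit:
    def test_exact_on_synthetic_histogram(self):
        # counts proportional to k^-2 for k = 1..8
        degrees = []
        for k in range(1, 9):
            degrees += [k] * int(round(1000 * k**-2.0))
        assert fit_powerlaw_exponent(degrees) == pytest.approx(2.0, abs=0.01)

    def test_degenerate_inputs_give_nan(self):
        assert np.isnan(fit_powerlaw_exponent([3, 3, 3]))
        assert np.isnan(fit_powerlaw_exponent([]))
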