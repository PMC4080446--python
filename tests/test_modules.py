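"""Dense-module mining and the cumulative hypergeometric interplay test,
against enumeration oracles and planted structure."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinet import hypergeom_upper, interplay, mcode_modules, mcode_weights
from epinet.types import Module, ModuleSet


def enumeration_upper_tail(N, M, H, x):
    """Brute-force P(X >= x): enumerate all C(N, H) draws."""
    marked = set(range(M))
    hits = total = 0
    for draw in itertools.combinations(range(N), H):
        total += 1
        if len(marked.intersection(draw)) >= x:
            hits += 1
    return hits / total


class TestHypergeomUpper:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper(100, 10, 5, 0) == 1.0

    def test_worked_small_case(self):
        # C(10,5)=252 draws; 66 contain >= 3 of the 4 marked genes
        assert hypergeom_upper(10, 4, 5, 3) == pytest.approx(66 / 252)
        assert enumeration_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_monotone_nonincreasing_in_overlap(self):
        ps = [hypergeom_upper(50, 12, 9, x) for x in range(10)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_point_probabilities_sum_to_one(self):
        # successive tail differences are the pmf; it must sum to 1
        for N, M, H in [(30, 7, 11), (100, 20, 5), (12, 6, 6)]:
            tails = [hypergeom_upper(N, M, H, x) for x in range(min(M, H) + 1)]
            pmf = [a - b for a, b in zip(tails, tails[1:])] + [tails[-1]]
            assert sum(pmf) == pytest.approx(1.0, abs=1e-12)
            # and the lowest feasible tail is exactly 1
            lo = max(0, M + H - N)
            assert hypergeom_upper(N, M, H, lo) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import hypergeom

        for N, M, H, x in [(2060, 6, 5, 4), (500, 40, 30, 10), (50, 25, 25, 20)]:
            assert hypergeom_upper(N, M, H, x) == pytest.approx(
                float(hypergeom.sf(x - 1, N, M, H)), rel=1e-9
            )

    @given(st.integers(1, 12), st.data())
    @settings(deadline=None, max_examples=40)
    def test_agrees_with_enumeration(self, N, data):
        M = data.draw(st.integers(0, N))
        H = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, min(M, H)))
        assert hypergeom_upper(N, M, H, x) == pytest.approx(
            enumeration_upper_tail(N, M, H, x), abs=1e-12
        )

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(10, 12, 5, 3)
        with pytest.raises(ValueError):
            hypergeom_upper(10, 4, 5, 5)


class TestMcodeWeights:
    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_node("a")
        assert mcode_weights(g)["a"] == 0.0

    def test_k4_vertex(self):
        g = nx.complete_graph(4)
        w = mcode_weights(g)
        assert all(v == pytest.approx(3.0) for v in w.values())

    def test_star_center(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        w = mcode_weights(g)
        # closed neighborhood is the whole star: 1-core, density 5/15
        assert w[0] == pytest.approx(1 * 5 / 15)

    def test_matches_peeling_oracle(self):
        g = nx.gnp_random_graph(25, 0.25, seed=10)

        def core_numbers_peeling(h):
            h = h.copy()
            core = {}
            k = 0
            while h.number_of_nodes():
                while True:
                    low = [v for v in h if h.degree(v) <= k]
                    if not low:
                        break
                    for v in low:
                        core[v] = k
                        h.remove_node(v)
                k += 1
            return core

        w = mcode_weights(g, degree_cutoff=0)
        for v in g:
            nbrs = set(g.neighbors(v))
            if not nbrs:
                assert w[v] == 0.0
                continue
            closed = g.subgraph(nbrs | {v})
            core = core_numbers_peeling(closed)
            kmax = max(core.values())
            core_nodes = [u for u, k in core.items() if k >= kmax]
            sub = closed.subgraph(core_nodes)
            n = sub.number_of_nodes()
            density = 2 * sub.number_of_edges() / (n * (n - 1)) if n > 1 else 0
            assert w[v] == pytest.approx(kmax * density)


class TestMcodeModules:
    def test_empty_graph(self):
        assert len(mcode_modules(nx.Graph())) == 0

    def test_two_cliques_linked_by_bridge_node_recovered_separately(self):
        g = nx.Graph()
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        g.add_edges_from(itertools.combinations(a, 2))
        g.add_edges_from(itertools.combinations(b, 2))
        g.add_edges_from([("a0", "w"), ("w", "b0")])  # low-weight bridge node
        mods = mcode_modules(g, min_size=3)
        found = {frozenset(m.genes) for m in mods}
        assert frozenset(a) in found and frozenset(b) in found

    def test_planted_community_recovery(self):
        rng = np.random.default_rng(11)
        n, k = 200, 25
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in itertools.combinations(range(n), 2):
            p = 0.9 if (i < k and j < k) else 0.02
            if rng.random() < p:
                g.add_edge(i, j)
        mods = mcode_modules(g, min_size=3)
        planted = set(range(k))
        best = max(mods, key=lambda m: len(set(m.genes) & planted))
        jac = len(set(best.genes) & planted) / len(set(best.genes) | planted)
        assert jac >= 0.8

    def test_modules_are_vertex_disjoint(self):
        g = nx.barabasi_albert_graph(150, 4, seed=12)
        mods = mcode_modules(g, min_size=3)
        seen = set()
        for m in mods:
            assert not (m.genes & seen)
            seen |= m.genes

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(40, 0.2, seed=13)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g})
        mapping = {v: f"x{v}" for v in g}  # order-preserving relabel
        h = nx.relabel_nodes(g, mapping)
        mods_g = {frozenset(mapping[v] for v in m.genes)
                  for m in mcode_modules(g, min_size=3)}
        mods_h = {frozenset(m.genes) for m in mcode_modules(h, min_size=3)}
        assert mods_g == mods_h

    def test_fluff_not_supported(self):
        with pytest.raises(NotImplementedError):
            mcode_modules(nx.complete_graph(4), fluff=True)


class TestInterplay:
    def make_sets(self, meth_genes, chrom_genes):
        return (
            ModuleSet([Module("A1", frozenset(meth_genes), 1.0)], "TMSN"),
            ModuleSet([Module("B1", frozenset(chrom_genes), 1.0)], "TCSN"),
        )

    def test_disjoint_modules_are_not_candidates(self):
        meth, chrom = self.make_sets({"a", "b", "c"}, {"x", "y", "z"})
        res = interplay(meth, chrom, set("abcxyz") | {"q"})
        assert len(res) == 1
        assert not res[0].tested and not res[0].significant

    def test_overlap_two_excluded_even_if_p_small(self):
        meth, chrom = self.make_sets({"a", "b", "c"}, {"a", "b", "z"})
        res = interplay(meth, chrom, set("abcz"), min_overlap=3)
        assert res[0].overlap_size == 2
        assert not res[0].tested
        assert math.isnan(res[0].p_bonferroni)

    def test_bonferroni_factor_counts_candidates(self):
        meth = ModuleSet(
            [Module("A1", frozenset("abcd"), 1.0),
             Module("A2", frozenset("efgh"), 1.0)], "TMSN",
        )
        chrom = ModuleSet(
            [Module("B1", frozenset("abce"), 1.0),
             Module("B2", frozenset("efgi"), 1.0)], "TCSN",
        )
        bg = set("abcdefghi") | set(map(str, range(20)))
        res = interplay(meth, chrom, bg, min_overlap=3)
        tested = [r for r in res if r.tested]
        assert len(tested) == 2  # A1xB1 overlap 3, A2xB2 overlap 3
        for r in tested:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 2))

    def test_background_must_cover_module_genes(self):
        meth, chrom = self.make_sets({"a", "b", "c"}, {"a", "b", "c"})
        with pytest.raises(ValueError):
            interplay(meth, chrom, {"a", "b"})

    def test_explicit_background_size(self):
        meth, chrom = self.make_sets({"a", "b", "c"}, {"a", "b", "c"})
        res = interplay(meth, chrom, set("abc"), N=100)
        assert res[0].background_size == 100
        assert res[0].significant
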