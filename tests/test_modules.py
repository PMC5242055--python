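"""Scored networks, spin-glass communities, greedy MWCS, module significance."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from epimodules.modules import (
    Module,
    build_scored_network,
    greedy_mwcs,
    module_significance,
    rank_modules,
    spinglass_modules,
)


class FakeScore:
    def __init__(self, fisher_score, combined_p):
        self.fisher_score = fisher_score
        self.combined_p = combined_p


def scored(edges, scores=None):
    scores = scores or {}
    return build_scored_network(edges, {g: FakeScore(s, np.exp(-s / 2)) for g, s in scores.items()})


class TestBuildScoredNetwork:
    def test_largest_component_kept(self):
        g = scored([("A", "B"), ("B", "C"), ("C", "D"), ("X", "Y")])
        assert set(g.nodes) == {"A", "B", "C", "D"}

    def test_duplicate_and_self_edges_collapse(self):
        g = scored([("A", "B"), ("B", "A"), ("A", "A"), ("B", "C")])
        assert g.number_of_edges() == 2

    def test_missing_score_flagged(self):
        g = scored([("A", "B"), ("B", "C")], {"A": 4.0, "B": 2.0})
        assert g.nodes["C"]["no_data"]
        assert g.nodes["C"]["combined_p"] == 1.0
        assert g.nodes["C"]["fisher_score"] == 0.0
        assert not g.nodes["A"]["no_data"]

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_scored_network([], {})


def two_cliques(n=10):
    g1 = nx.complete_graph(range(n))
    g2 = nx.complete_graph(range(n, 2 * n))
    g = nx.union(g1, g2)
    g.add_edge(0, n)  # single bridge
    return [(str(a), str(b)) for a, b in g.edges]


class TestSpinglassModules:
    def test_two_cliques_recovered(self):
        """Two 10-cliques joined by a bridge: the optimal 2-partition is the cliques."""
        edges = two_cliques(10)
        net = scored(edges, {str(i): 1.0 for i in range(20)})
        mods = spinglass_modules(net, min_size=8, max_size=100, seed=7)
        assert len(mods) == 2
        parts = sorted((frozenset(int(g) for g in m.genes) for m in mods), key=min)
        assert parts[0] == frozenset(range(10))
        assert parts[1] == frozenset(range(10, 20))

    def test_ring_contract(self):
        edges = [(str(i), str((i + 1) % 30)) for i in range(30)]
        net = scored(edges, {str(i): 1.0 for i in range(30)})
        mods = spinglass_modules(net, min_size=8, max_size=100, seed=3)
        for m in mods:
            assert 8 <= len(m.genes) <= 100
            assert nx.is_connected(net.subgraph(m.genes))

    def test_seeded_determinism(self):
        edges = two_cliques(10)
        net = scored(edges, {str(i): float(i % 5) for i in range(20)})
        a = spinglass_modules(net, seed=11)
        b = spinglass_modules(net, seed=11)
        assert [m.genes for m in a] == [m.genes for m in b]

    def test_too_small_network_rejected(self):
        net = scored([("A", "B"), ("B", "C")])
        with pytest.raises(ValueError, match="minimum module size"):
            spinglass_modules(net, min_size=8)


def brute_force_mwcs(g, weights):
    """Exhaustive maximum-weight connected subgraph on tiny graphs."""
    nodes = list(g.nodes)
    best, best_set = -np.inf, None
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if nx.is_connected(g.subgraph(subset)):
                total = sum(weights[n] for n in subset)
                if total > best:
                    best, best_set = total, set(subset)
    return best, best_set


class TestGreedyMwcs:
    def _network(self, edges, weights):
        g = build_scored_network(edges, {n: FakeScore(w, 0.5) for n, w in weights.items()})
        return g

    def test_star_keeps_center_only(self):
        edges = [("C", f"L{i}") for i in range(5)]
        weights = {"C": 5.0, **{f"L{i}": -1.0 for i in range(5)}}
        net = self._network(edges, weights)
        m = greedy_mwcs(net, score_offset=0.0)
        assert m.genes == frozenset({"C"})

    def test_negative_bridge_worth_crossing(self):
        net = self._network([("A", "B"), ("B", "C")], {"A": 2.0, "B": -1.0, "C": 3.0})
        m = greedy_mwcs(net, score_offset=0.0)
        assert m.genes == frozenset({"A", "B", "C"})
        assert m.modularity_contribution == pytest.approx(4.0)

    def test_all_negative_returns_best_single(self):
        net = self._network([("A", "B"), ("B", "C")], {"A": 1.0, "B": 2.0, "C": 0.5})
        m = greedy_mwcs(net, score_offset=10.0)
        assert m.genes == frozenset({"B"})

    def test_near_optimal_on_random_graphs(self, rng):
        """Greedy reaches >= 80% of the brute-force optimum on most 8-node graphs."""
        ok, total = 0, 30
        for trial in range(total):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1e6)))
            if not nx.is_connected(g):
                g = g.subgraph(max(nx.connected_components(g), key=len))
            if g.number_of_nodes() < 3:
                continue
            weights = {str(n): float(w) for n, w in zip(g.nodes, rng.normal(0, 2, g.number_of_nodes()))}
            edges = [(str(a), str(b)) for a, b in g.edges]
            net = self._network(edges, weights)
            m = greedy_mwcs(net, score_offset=0.0)
            opt, _ = brute_force_mwcs(nx.relabel_nodes(g, str), weights)
            got = m.modularity_contribution
            if opt <= 0:
                ok += got == pytest.approx(opt)
            else:
                ok += got >= 0.8 * opt
        assert ok / total >= 0.9


class TestModuleSignificance:
    def test_all_p_one(self):
        chi2, df, p = module_significance({"a", "b", "c"}, {"a": 1.0, "b": 1.0, "c": 1.0})
        assert chi2 == 0.0 and df == 6 and p == 1.0

    def test_single_gene_exponential_tail(self):
        chi2, df, p = module_significance({"a"}, {"a": float(np.exp(-1))})
        assert chi2 == pytest.approx(2.0)
        assert df == 2
        assert p == pytest.approx(np.exp(-1), abs=1e-9)  # chi2_2 survival = exp(-x/2)

    def test_null_rejection_rate(self, rng):
        rejections = 0
        n = 3000
        for _ in range(n):
            ps = {str(i): float(p) for i, p in enumerate(rng.uniform(size=5))}
            _, _, p = module_significance(set(ps), ps)
            rejections += p < 0.05
        assert 0.03 < rejections / n < 0.07


class TestRankModules:
    def _module(self, mid, p, mean_score, k=2):
        genes = frozenset(f"{mid}_{i}" for i in range(k))
        return Module(mid, genes, 1.0, 2 * k, p, mean_score)

    def test_order_by_p_then_score(self):
        mods = [
            self._module("m1", 0.5, 1.0),
            self._module("m2", 0.01, 2.0),
            self._module("m3", 0.01, 3.0),
        ]
        ranked = rank_modules(mods)
        assert [m.module_id for m in ranked] == ["m3", "m2", "m1"]

    def test_empty(self):
        assert rank_modules([]) == []

    def test_permutation(self, rng):
        mods = [self._module(f"m{i}", float(p), 0.0) for i, p in enumerate(rng.uniform(size=8))]
        ranked = rank_modules(mods)
        assert sorted(m.module_id for m in ranked) == sorted(m.module_id for m in mods)
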