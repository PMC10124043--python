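"""Random-walk nulls, rooted canonical forms and motif enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_graph
from facin.structure_motifs import (
    RootedSubgraph,
    canonical_form,
    count_motifs,
    generate_null,
    motif_enrichment,
    random_walk_subgraph,
)


def rooted_isomorphic(e1, r1, e2, r2):
    """Brute-force rooted isomorphism via networkx with root labels."""
    def build(edges, root):
        g = nx.Graph(edges)
        g.add_node(root)
        nx.set_node_attributes(g, {n: n == root for n in g.nodes}, "is_root")
        return g

    return nx.is_isomorphic(build(e1, r1), build(e2, r2),
                            node_match=lambda a, b: a["is_root"] == b["is_root"])


class TestRandomWalk:
    def test_structural_constraints(self):
        g = random_graph(n_nodes=30, edge_prob=0.2, seed=3)
        nxg = g.to_networkx()
        for seed in range(10):
            rs = random_walk_subgraph(g, 5, max_edges=10, hops=2, seed=seed)
            assert len(rs.edges) <= 10
            dist = nx.single_source_shortest_path_length(nxg, 5, cutoff=2)
            nodes = {u for e in rs.edges for u in e}
            assert nodes <= set(dist)
            if rs.edges:
                sub = nx.Graph(rs.edges)
                sub.add_node(5)
                assert nx.is_connected(sub)

    def test_deterministic_under_seed(self):
        g = random_graph(n_nodes=20, edge_prob=0.3, seed=1)
        a = random_walk_subgraph(g, 2, seed=42)
        b = random_walk_subgraph(g, 2, seed=42)
        assert a.edges == b.edges

    def test_isolated_node_empty(self):
        g = random_graph(n_nodes=6, seed=0)
        g.edges = {e: w for e, w in g.edges.items() if 0 not in e}
        assert random_walk_subgraph(g, 0, seed=1).edges == []

    def test_k5_visited_node_distribution_matches_independent_walk(self):
        # same walk rules, separate code path and rng
        import random as pyrandom

        k5_edges = {(i, j): 3 for i in range(5) for j in range(i + 1, 5)}
        g = random_graph(n_nodes=5, edge_prob=0.0, seed=0)
        g.edges = k5_edges
        n_draws, max_edges = 1000, 4

        def mine():
            counts = np.zeros(6)
            for s in range(n_draws):
                rs = random_walk_subgraph(g, 0, max_edges=max_edges, seed=s)
                counts[len({u for e in rs.edges for u in e})] += 1
            return counts / n_draws

        def independent():
            rng = pyrandom.Random(999)
            counts = np.zeros(6)
            for _ in range(n_draws):
                cur, seen = 0, set()
                while len(seen) < max_edges:
                    nxt = rng.choice([v for v in range(5) if v != cur])
                    seen.add((min(cur, nxt), max(cur, nxt)))
                    cur = nxt
                counts[len({u for e in seen for u in e})] += 1
            return counts / n_draws

        tv = 0.5 * np.abs(mine() - independent()).sum()
        assert tv < 0.08

    def test_generate_null_sizes(self):
        g = random_graph(n_nodes=20, edge_prob=0.3, seed=1)
        out = generate_null(g, sites=[1, 2, 3], n_samples=2, seed=0)
        assert len(out) == 6


class TestCanonicalForm:
    def test_relabeling_invariance_on_paths(self):
        a = canonical_form([(0, 1), (1, 2)], root=0)
        b = canonical_form([(7, 42), (42, 13)], root=7)
        assert a == b

    def test_path_end_vs_star_center_differ(self):
        path = canonical_form([(0, 1), (1, 2), (2, 3)], root=0)
        star = canonical_form([(0, 1), (0, 2), (0, 3)], root=0)
        assert path != star

    def test_root_placement_matters(self):
        end = canonical_form([(0, 1), (1, 2)], root=0)
        middle = canonical_form([(0, 1), (1, 2)], root=1)
        assert end != middle

    @given(st.integers(0, 10_000), st.permutations(list(range(6))))
    @settings(max_examples=60, deadline=None)
    def test_congruence_under_node_permutation(self, seed, perm):
        rng = np.random.default_rng(seed)
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.4]
        nxg = nx.Graph(edges)
        nxg.add_nodes_from(range(6))
        comp = nx.node_connected_component(nxg, 0)
        kept = [e for e in edges if e[0] in comp and e[1] in comp]
        mapped = [(perm[i], perm[j]) for i, j in kept]
        assert canonical_form(kept, 0) == canonical_form(mapped, perm[0])

    def test_agreement_with_bruteforce_isomorphism_sample(self):
        rng = np.random.default_rng(7)
        graphs = []
        for _ in range(50):
            n = rng.integers(2, 7)
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.5]
            nxg = nx.Graph(edges)
            nxg.add_nodes_from(range(n))
            comp = nx.node_connected_component(nxg, 0)
            graphs.append([e for e in edges if e[0] in comp and e[1] in comp])
        labels = [canonical_form(e, 0) for e in graphs]
        for (e1, l1), (e2, l2) in itertools.combinations(zip(graphs, labels), 2):
            assert (l1 == l2) == rooted_isomorphic(e1, 0, e2, 0)


class TestCountingAndEnrichment:
    def test_identical_topologies_one_class(self):
        chains = [RootedSubgraph(root=r, edges=[(r, r + 100), (r + 100, r + 200)])
                  for r in range(5)]
        classes = count_motifs(chains)
        assert len(classes) == 1 and classes[0].count == 5

    def test_counts_conserve_input_size(self):
        g = random_graph(n_nodes=25, edge_prob=0.25, seed=9)
        subs = [random_walk_subgraph(g, s, max_edges=5, seed=s) for s in range(12)]
        subs = [s for s in subs if s.edges]
        classes = count_motifs(subs)
        assert sum(c.count for c in classes) == len(subs)

    def test_cascade_and_bifurcate_are_distinct_classes(self):
        cascade = RootedSubgraph(root=0, edges=[(0, 1), (1, 2)])
        bifurcate = RootedSubgraph(root=0, edges=[(0, 1), (1, 2), (1, 3)])
        assert len(count_motifs([cascade, bifurcate])) == 2

    def test_order_independent(self):
        subs = [RootedSubgraph(0, [(0, 1)]), RootedSubgraph(0, [(0, 1), (1, 2)]),
                RootedSubgraph(0, [(0, 1)])]
        a = [(c.label, c.count) for c in count_motifs(subs)]
        b = [(c.label, c.count) for c in count_motifs(list(reversed(subs)))]
        assert a == b

    def test_identical_observed_and_null_ratio_one(self):
        subs = [RootedSubgraph(0, [(0, 1)]), RootedSubgraph(0, [(0, 1), (1, 2)])]
        obs = count_motifs(subs)
        rep = motif_enrichment(obs, obs)
        assert np.allclose(rep["ratio"], 1.0)

    def test_motif_absent_from_null_uses_pseudo_frequency(self):
        obs = count_motifs([RootedSubgraph(0, [(0, 1)])] * 50 +
                           [RootedSubgraph(0, [(0, 1), (1, 2)])] * 50)
        null = count_motifs([RootedSubgraph(0, [(0, 1), (1, 2)])] * 100)
        rep = motif_enrichment(obs, null).set_index("motif")
        lone = canonical_form([(0, 1)], 0)
        assert np.isinf(rep.loc[lone, "ratio"])
        assert rep.loc[lone, "null_count"] == 0
        assert 0 < rep.loc[lone, "p_value"] < 1e-6

    def test_planted_cascades_flagged_enriched(self):
        g = random_graph(n_nodes=40, edge_prob=0.25, seed=11)
        cascades = [RootedSubgraph(root=s, edges=[(s, s + 1), (s + 1, s + 2)])
                    for s in range(30)]
        null = count_motifs([rs for rs in
                             (random_walk_subgraph(g, s % 40, max_edges=10, seed=s)
                              for s in range(60)) if rs.edges])
        rep = motif_enrichment(count_motifs(cascades), null).set_index("motif")
        cascade_label = canonical_form([(0, 1), (1, 2)], 0)
        assert rep.loc[cascade_label, "p_value"] < 0.01

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment(count_motifs([RootedSubgraph(0, [(0, 1)])]), [])
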