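"""FaCIN extraction, bottleneck classification and site-targeted betweenness."""

import numpy as np
import pytest

from _oracles import betweenness_by_path_enumeration
from conftest import random_graph
from facin.explainer import Explanation
from facin.facin_core import (
    FaCIN,
    betweenness_to_site,
    classify_bottleneck,
    extract_facin,
    facin_stats,
    facins_from_jsonl,
    facins_to_jsonl,
    neck_interactions_table,
)
from facin.genome_io import ContactGraph, bin_genome


def make_graph(n, edges, chrom="chrT", labels=None):
    return ContactGraph(
        chrom=chrom,
        bins=bin_genome({chrom: n * 5000}, 5000),
        edges={(min(i, j), max(i, j)): w for (i, j), w in edges.items()},
        features=None,
        labels=np.asarray(labels) if labels is not None else np.zeros(n, dtype=np.int64),
    )


def make_expl(center, ranked_pairs, scores=None):
    if scores is None:
        scores = np.linspace(0.95, 0.5, len(ranked_pairs))
    edges = [(i, j, float(s), float("nan")) for (i, j), s in zip(ranked_pairs, scores)]
    return Explanation(center=center, prediction=0.9, predicted_label=1,
                       edges=edges, feature_scores=np.zeros(1346))


def make_facin(site, edges, n=None):
    nodes = sorted({site} | {u for e in edges for u in e})
    f = FaCIN(site=site, nodes=nodes, edges=list(edges))
    return classify_bottleneck(f)


class TestExtractFacin:
    def test_small_computation_graph_keeps_all_edges(self):
        pairs = [(0, 1), (1, 2), (0, 3), (3, 4), (1, 5), (5, 6), (0, 7)]
        g = make_graph(8, {p: 5 for p in pairs})
        f = extract_facin(make_expl(0, pairs), g, max_edges=10)
        assert sorted(f.edges) == sorted(pairs)

    def test_at_most_ten_edges_connected_and_contains_site(self):
        g = random_graph(n_nodes=14, edge_prob=0.5, seed=8)
        pairs = sorted(g.edges)
        f = extract_facin(make_expl(3, pairs), g, max_edges=10)
        assert len(f.edges) <= 10
        assert 3 in f.nodes
        # connectivity to the site
        import networkx as nx

        sub = nx.Graph(f.edges)
        sub.add_node(3)
        assert nx.is_connected(sub)

    def test_disconnected_top_edge_waits_for_connector(self):
        # rank-1 (2,3) detaches from site 0 until rank-3 (0,2) admits it
        g = make_graph(5, {(2, 3): 5, (3, 4): 5, (0, 2): 5})
        expl = make_expl(0, [(2, 3), (3, 4), (0, 2)])
        f = extract_facin(expl, g, max_edges=10)
        assert f.edges == [(0, 2), (2, 3), (3, 4)]

    def test_matches_independent_greedy_on_toy(self):
        # independent re-implementation of the greedy-connected admission
        g = random_graph(n_nodes=8, edge_prob=0.5, seed=1)
        ranked = sorted(g.edges)
        site, max_edges = 0, 4
        f = extract_facin(make_expl(site, ranked), g, max_edges=max_edges)

        admitted, comp = [], {site}
        while len(admitted) < max_edges:
            nxt = next((e for e in ranked
                        if e not in admitted and (e[0] in comp or e[1] in comp)), None)
            if nxt is None:
                break
            admitted.append(nxt)
            comp.update(nxt)
        assert f.edges == admitted

    def test_isolated_site_yields_single_node_facin(self):
        g = make_graph(4, {(1, 2): 3})
        f = extract_facin(make_expl(0, []), g)
        assert f.nodes == [0] and f.edges == []
        assert f.neck_neighbors == [] and f.other_neighbors == []

    def test_invariant_to_graph_edge_dict_order(self):
        g1 = random_graph(n_nodes=10, edge_prob=0.4, seed=2)
        g2 = make_graph(10, dict(reversed(list(g1.edges.items()))))
        g2.labels = g1.labels
        expl = make_expl(1, sorted(g1.edges))
        assert extract_facin(expl, g1).edges == extract_facin(expl, g2).edges

    def test_rank_by_delta_v_reorders(self):
        g = make_graph(4, {(0, 1): 5, (0, 2): 5, (0, 3): 5})
        edges = [(0, 1, 0.9, 0.01), (0, 2, 0.8, 0.5), (0, 3, 0.7, 0.2)]
        expl = Explanation(center=0, prediction=0.9, predicted_label=1,
                           edges=edges, feature_scores=np.zeros(1346))
        f_mask = extract_facin(expl, g, rank_by="mask")
        f_dv = extract_facin(expl, g, rank_by="delta_v")
        assert f_mask.edges[0] == (0, 1) and f_dv.edges[0] == (0, 2)
        with pytest.raises(ValueError):
            extract_facin(expl, g, rank_by="nope")

    def test_lengths_and_intensities_recorded(self):
        g = make_graph(50, {(10, 40): 7, (0, 10): 3})
        f = extract_facin(make_expl(10, [(10, 40), (0, 10)]), g)
        assert f.lengths[(10, 40)] == 150000
        assert f.intensities[(10, 40)] == 7


class TestClassifyBottleneck:
    def test_path_partition(self):
        f = make_facin(2, [(0, 1), (1, 2)])  # a-b-site
        assert f.neck_neighbors == [1] and f.other_neighbors == [0]
        assert f.neck_interactions == [(1, 2)] and f.other_interactions == [(0, 1)]

    def test_star_all_neck(self):
        f = make_facin(0, [(0, 1), (0, 2), (0, 3)])
        assert f.neck_neighbors == [1, 2, 3] and f.other_neighbors == []

    def test_single_node_empty_partitions(self):
        f = classify_bottleneck(FaCIN(site=5, nodes=[5], edges=[]))
        assert f.neck_neighbors == [] and f.neck_interactions == []


class TestBetweenness:
    def test_path_scores(self):
        f = make_facin(2, [(0, 1), (1, 2)])
        s = betweenness_to_site(f)
        assert s == {1: 1.0, 0: 0.0}

    def test_star_leaves_zero(self):
        f = make_facin(0, [(0, 1), (0, 2), (0, 3), (0, 4)])
        assert set(betweenness_to_site(f).values()) == {0.0}

    def test_diamond_fractional_split(self):
        f = make_facin(3, [(0, 1), (0, 2), (1, 3), (2, 3)])
        s = betweenness_to_site(f)
        assert s[1] == pytest.approx(0.5) and s[2] == pytest.approx(0.5)
        assert s[0] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_path_enumeration_oracle(self, seed):
        g = random_graph(n_nodes=8, edge_prob=0.45, seed=seed)
        import networkx as nx

        nxg = g.to_networkx()
        comp = max(nx.connected_components(nxg), key=len)
        site = min(comp)
        edges = [e for e in g.edges if e[0] in comp and e[1] in comp]
        f = make_facin(site, edges)
        got = betweenness_to_site(f)
        ref = betweenness_by_path_enumeration(nxg.subgraph(comp), site)
        for v in ref:
            assert got[v] == pytest.approx(ref[v], abs=1e-12)


class TestStatsAndIO:
    def test_neck_count_histogram_and_lengths(self):
        g = make_graph(50, {(10, 40): 7, (10, 12): 2, (12, 20): 4})
        g.labels[10] = 1
        f = extract_facin(make_expl(10, [(10, 40), (10, 12), (12, 20)]), g)
        stats = facin_stats([f])
        assert stats["neck_count_histogram"] == {2: 1}
        assert sorted(stats["dsb_neck_lengths_bp"]) == [10000, 150000]
        assert stats["non_dsb_neck_lengths_bp"] == []

    def test_totals_conserved_over_sites(self):
        g = random_graph(n_nodes=12, edge_prob=0.5, seed=4)
        facins = [extract_facin(make_expl(s, sorted(g.edges)), g, max_edges=5)
                  for s in range(4)]
        stats = facin_stats(facins)
        assert sum(k * v for k, v in stats["neck_count_histogram"].items()) == \
            sum(len(f.neck_interactions) for f in facins)

    def test_jsonl_round_trip_and_bedpe(self, tmp_path):
        g = make_graph(50, {(10, 40): 7, (10, 12): 2})
        f = extract_facin(make_expl(10, [(10, 40), (10, 12)]), g)
        facins_to_jsonl([f], tmp_path / "f.jsonl")
        back = facins_from_jsonl(tmp_path / "f.jsonl")[0]
        assert back.site == f.site and back.edges == f.edges
        assert back.neck_interactions == f.neck_interactions
        table = neck_interactions_table([f])
        assert len(table) == 2
        assert set(table.columns) >= {"chrom1", "start1", "end1", "start2", "end2"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            facin_stats([])
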