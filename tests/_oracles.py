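"""Independent reference computations used as test oracles.

These deliberately re-derive model quantities with explicit Python loops and
dense per-node arithmetic, sharing no code path with the vectorized
scatter/gather implementation they check.
"""

import numpy as np

from facin.graph_model import positional_encoding


def _softmax(x):
    e = np.exp(x - np.max(x))
    return e / e.sum()


def dense_forward(model, graph):
    """Loop-based forward pass.

    Returns (per-layer states, per-node probabilities, attention dict
    {(layer, head, node): coefficient array}).
    """
    cfg = model.config
    P = {k: t.data for k, t in model.params.items()}
    n = graph.n_nodes
    deg = graph.degrees()
    X = model._ablate(graph.features)
    x = X @ P["W_in"] + P["b_in"]
    if cfg.use_positional:
        x = x + positional_encoding(np.arange(n), cfg.hidden_dim)
    if cfg.use_centrality:
        x = x + P["cent_emb"][np.minimum(deg, cfg.degree_cap)]

    he = {}
    for (i, j), w in graph.edges.items():
        if cfg.zero_adjacency or not cfg.use_edge_encoding:
            c = 0.0
        elif cfg.edge_transform == "log1p":
            c = np.log1p(w)
        else:
            c = w * cfg.edge_scale
        he[(i, j)] = np.array([c]) @ P["W_edge"] + P["b_edge"]

    nbrs = {i: [] for i in range(n)}
    for (i, j) in graph.edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    for i in nbrs:
        nbrs[i].sort()

    def edge_feat(i, j):
        return he[(min(i, j), max(i, j))]

    h = x
    states = []
    attention = {}
    for l in range(cfg.n_layers):
        head_outs = []
        for k in range(cfg.n_heads):
            W_N, W_E, W = P[f"W_N_{l}_{k}"], P[f"W_E_{l}_{k}"], P[f"W_{l}_{k}"]
            bi, bj, be = P[f"beta_i_{l}_{k}"], P[f"beta_j_{l}_{k}"], P[f"beta_e_{l}_{k}"]
            b = P[f"b_{l}_{k}"]
            out = np.zeros((n, W.shape[1]))
            for i in range(n):
                js = nbrs[i]
                if js:
                    scores = []
                    for j in js:
                        s = (h[i] @ W_N) @ bi + (h[j] @ W_N) @ bj + (edge_feat(i, j) @ W_E) @ be
                        scores.append(s if s > 0 else cfg.leaky_slope * s)
                    alpha = _softmax(np.asarray(scores))
                    attention[(l, k, i)] = alpha
                    m = sum(a * (h[j] @ W) for a, j in zip(alpha, js))
                else:
                    m = np.zeros(W.shape[1])
                out[i] = np.maximum(m + b, 0.0)
            head_outs.append(out)
        if l == cfg.n_layers - 1:
            h = np.mean(head_outs, axis=0)
        else:
            h = np.concatenate(head_outs, axis=1)
        states.append(h)

    jk = np.concatenate(states, axis=1) if cfg.use_jk else states[-1]
    edge_term = np.zeros((n, cfg.hidden_dim))
    for i in range(n):
        if nbrs[i]:
            edge_term[i] = sum(edge_feat(i, j) for j in nbrs[i]) / max(deg[i], 1)
    z = (np.concatenate([jk, edge_term], axis=1) @ P["W_out"] + P["b_out"]).ravel()
    return states, 1.0 / (1.0 + np.exp(-z)), attention


def betweenness_by_path_enumeration(nx_graph, site):
    """Targeted betweenness via explicit enumeration of all shortest paths."""
    import networkx as nx

    scores = {v: 0.0 for v in nx_graph.nodes if v != site}
    for s in nx_graph.nodes:
        if s == site or not nx.has_path(nx_graph, s, site):
            continue
        paths = list(nx.all_shortest_paths(nx_graph, s, site))
        for v in scores:
            if v == s:
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            scores[v] += through / len(paths)
    return scores
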