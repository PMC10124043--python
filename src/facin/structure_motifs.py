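"""Topological motif discovery over FaCINs against random-walk nulls.

FaCIN topologies (rooted at the prediction site) are grouped into
isomorphism classes via an exact canonical form, counted, and compared with
null subgraphs generated by seeded random walks on the same contact graph
under the same structural constraints (connected, rooted, <= 10 edges,
within the 2-hop radius).  Enrichment per motif is an exact one-sided
binomial test of the observed count against the null frequency.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .facin_core import FaCIN
from .genome_io import ContactGraph

__all__ = [
    "MotifClass",
    "RootedSubgraph",
    "random_walk_subgraph",
    "canonical_form",
    "count_motifs",
    "motif_enrichment",
    "generate_null",
]

Edge = Tuple[int, int]


@dataclass
class RootedSubgraph:
    root: int
    edges: List[Edge]


@dataclass
class MotifClass:
    """One rooted-isomorphism class of subgraph topologies."""

    label: str
    count: int
    members: List[int] = field(default_factory=list)  # root node ids
    example: Optional[RootedSubgraph] = None


# ---------------------------------------------------------------------------
# random-walk null
# ---------------------------------------------------------------------------

def _adjacency(graph: ContactGraph) -> Dict[int, List[int]]:
    adj: Dict[int, List[int]] = {}
    for (i, j) in graph.edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for v in adj:
        adj[v].sort()
    return adj


def random_walk_subgraph(
    graph: ContactGraph,
    node: int,
    max_edges: int = 10,
    hops: int = 2,
    seed: int = 0,
) -> RootedSubgraph:
    """Seeded random walk collecting distinct traversed edges.

    The walk starts at the root; each step moves to a uniformly random
    neighbor, and a step that would leave the `hops`-radius around the root
    restarts the walk at the root instead.  It stops after `max_edges`
    distinct edges or once every reachable in-radius edge is collected.
    """
    if node < 0 or node >= graph.n_nodes:
        raise ValueError(f"node {node} not in graph")
    adj = _adjacency(graph)
    # nodes within the hop radius
    dist = {node: 0}
    q = deque([node])
    while q:
        u = q.popleft()
        if dist[u] == hops:
            continue
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    in_radius = set(dist)
    collectible = sum(
        1 for (i, j) in graph.edges if i in in_radius and j in in_radius
    )
    target = min(max_edges, collectible)
    rng = np.random.default_rng(seed)
    edges: List[Edge] = []
    seen: Set[Edge] = set()
    cur = node
    stall_limit = 200 * max(max_edges, 1)
    steps = 0
    while len(edges) < target and steps < stall_limit:
        steps += 1
        nbrs = adj.get(cur, ())
        if not nbrs:
            break
        nxt = nbrs[rng.integers(len(nbrs))]
        if nxt not in in_radius:
            cur = node
            continue
        key = (min(cur, nxt), max(cur, nxt))
        if key not in seen:
            seen.add(key)
            edges.append(key)
        cur = nxt
    return RootedSubgraph(root=node, edges=edges)


def generate_null(
    graph: ContactGraph,
    sites: Sequence[int],
    max_edges: int = 10,
    hops: int = 2,
    n_samples: int = 1,
    seed: int = 0,
) -> List[RootedSubgraph]:
    """Random-walk subgraphs for each site, n_samples walks per site."""
    out = []
    for rep in range(n_samples):
        for k, s in enumerate(sites):
            out.append(random_walk_subgraph(graph, s, max_edges, hops,
                                            seed=seed + 100003 * rep + k))
    return out


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------

def _wl_signatures(nodes: List[int], adj: Dict[int, List[int]], root: int) -> Dict[int, str]:
    sig = {v: ("R" if v == root else "x") for v in nodes}
    for _ in range(len(nodes)):
        new = {
            v: sig[v] + "|" + ",".join(sorted(sig[u] for u in adj[v]))
            for v in nodes
        }
        # compress to short canonical tokens to keep strings bounded
        token = {s: f"c{t}" for t, s in enumerate(sorted(set(new.values())))}
        new = {v: token[new[v]] + ("R" if v == root else "") for v in nodes}
        if len(set(new.values())) == len(set(sig.values())):
            sig = new
            break
        sig = new
    return sig


def _multiset_permutations(items):
    """Distinct permutations of a sequence with repeated elements."""
    items = sorted(items)
    n = len(items)
    out: List[List] = []

    def rec(prefix, remaining):
        if not remaining:
            out.append(prefix)
            return
        prev = object()
        for k, x in enumerate(remaining):
            if x == prev:
                continue
            prev = x
            rec(prefix + [x], remaining[:k] + remaining[k + 1:])

    rec([], items)
    return out


def canonical_form(edges: Iterable[Edge], root: int) -> str:
    """Exact canonical label of a connected rooted graph.

    Identical labels iff a root-preserving isomorphism exists; stable under
    arbitrary node relabeling.  Nodes are first partitioned by iterated
    neighborhood-refinement colors; the label is the minimum edge encoding
    over all color-preserving orderings.  Within a color class, vertices
    with identical neighbor sets are automorphic twins (common in bottleneck
    topologies, where many leaves hang off one neck node) — swapping them
    never changes the encoding, so only arrangements of distinct twin groups
    are enumerated, keeping the search tiny for <=10-edge graphs.
    """
    edges = [tuple(e) for e in edges]
    nodes = sorted({root} | {u for e in edges for u in e})
    adj: Dict[int, List[int]] = {v: [] for v in nodes}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    sig = _wl_signatures(nodes, adj, root)
    classes: Dict[str, List[int]] = {}
    for v in nodes:
        classes.setdefault(sig[v], []).append(v)

    # arrangements per class: permute twin groups, keep twins in fixed order
    class_arrangements = []
    for s in sorted(classes):
        members = classes[s]
        twin_groups: Dict[frozenset, List[int]] = {}
        for v in members:
            twin_groups.setdefault(frozenset(adj[v]), []).append(v)
        keys = sorted(twin_groups, key=sorted)
        key_seq = []
        for gk, group in sorted(twin_groups.items(), key=lambda kv: sorted(kv[0])):
            key_seq.extend([keys.index(gk)] * len(group))
        arrangements = []
        for perm in _multiset_permutations(key_seq):
            pools = {k: list(twin_groups[keys[k]]) for k in range(len(keys))}
            arrangements.append([pools[k].pop(0) for k in perm])
        class_arrangements.append(arrangements)

    best = None
    for parts in itertools.product(*class_arrangements):
        order = [v for part in parts for v in part]
        pos = {v: k for k, v in enumerate(order)}
        enc = (
            len(nodes),
            pos[root],
            tuple(sorted((min(pos[i], pos[j]), max(pos[i], pos[j])) for i, j in edges)),
        )
        if best is None or enc < best:
            best = enc
    return repr(best)


# ---------------------------------------------------------------------------
# counting and enrichment
# ---------------------------------------------------------------------------

def _as_rooted(item: Union[FaCIN, RootedSubgraph, Tuple[int, Sequence[Edge]]]) -> RootedSubgraph:
    if isinstance(item, FaCIN):
        return RootedSubgraph(root=item.site, edges=list(item.edges))
    if isinstance(item, RootedSubgraph):
        return item
    root, edges = item
    return RootedSubgraph(root=root, edges=list(edges))


def count_motifs(subgraphs: Sequence[Union[FaCIN, RootedSubgraph, Tuple]]) -> List[MotifClass]:
    """Group rooted subgraphs by canonical topology; counts conserve the input size."""
    if len(subgraphs) == 0:
        raise ValueError("at least one subgraph required")
    classes: Dict[str, MotifClass] = {}
    for item in subgraphs:
        rs = _as_rooted(item)
        label = canonical_form(rs.edges, rs.root)
        mc = classes.get(label)
        if mc is None:
            classes[label] = MotifClass(label=label, count=1, members=[rs.root], example=rs)
        else:
            mc.count += 1
            mc.members.append(rs.root)
    return sorted(classes.values(), key=lambda m: (-m.count, m.label))


def motif_enrichment(
    facin_classes: Sequence[MotifClass],
    null_classes: Sequence[MotifClass],
) -> pd.DataFrame:
    """Per-motif observed vs null counts, frequency ratio and binomial p-value.

    The null frequency of a motif absent from the null is set to the
    pseudo-frequency 0.5 / (n_null + 1) so a one-sided exact binomial test
    remains defined.
    """
    n_obs = sum(m.count for m in facin_classes)
    n_null = sum(m.count for m in null_classes)
    if n_null == 0:
        raise ValueError("null counting is empty")
    null_by_label = {m.label: m.count for m in null_classes}
    rows = []
    for m in facin_classes:
        nc = null_by_label.get(m.label, 0)
        p_null = nc / n_null if nc > 0 else 0.5 / (n_null + 1)
        p = binomtest(m.count, n_obs, p_null, alternative="greater").pvalue
        obs_freq = m.count / n_obs
        rows.append({
            "motif": m.label,
            "observed": m.count,
            "observed_freq": obs_freq,
            "null_count": nc,
            "null_freq": nc / n_null,
            "ratio": obs_freq / p_null if nc > 0 else float("inf"),
            "p_value": float(p),
        })
    return pd.DataFrame(rows).sort_values("observed", ascending=False).reset_index(drop=True)
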