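"""Fragility-associated chromatin interaction networks (FaCINs).

A site's FaCIN is the connected subgraph formed by up to 10 of the most
important edges of its explanation, always containing the prediction site.
Its 1-hop members joined to the site by retained direct edges are the neck
neighbors (the bottleneck elements); everything else is an "other"
neighbor/interaction.  A site-targeted betweenness score quantifies how
often each member lies on shortest paths between the remaining nodes and
the prediction site.
"""

from __future__ import annotations

import json
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .explainer import Explanation
from .genome_io import ContactGraph, DEFAULT_BIN_SIZE

__all__ = [
    "FaCIN",
    "extract_facin",
    "classify_bottleneck",
    "betweenness_to_site",
    "facin_stats",
    "facins_to_jsonl",
    "facins_from_jsonl",
    "neck_interactions_table",
]

MAX_FACIN_EDGES = 10


@dataclass
class FaCIN:
    """Connected <=10-edge explanation subgraph around one prediction site."""

    site: int
    nodes: List[int]
    edges: List[Tuple[int, int]]  # admission order
    neck_neighbors: List[int] = field(default_factory=list)
    neck_interactions: List[Tuple[int, int]] = field(default_factory=list)
    other_neighbors: List[int] = field(default_factory=list)
    other_interactions: List[Tuple[int, int]] = field(default_factory=list)
    lengths: Dict[Tuple[int, int], int] = field(default_factory=dict)  # bp, midpoint to midpoint
    intensities: Dict[Tuple[int, int], float] = field(default_factory=dict)
    site_label: Optional[int] = None
    chrom: Optional[str] = None
    bin_size: int = DEFAULT_BIN_SIZE

    def adjacency(self) -> Dict[int, List[int]]:
        adj: Dict[int, List[int]] = {u: [] for u in self.nodes}
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj


def extract_facin(
    explanation: Explanation,
    graph: ContactGraph,
    max_edges: int = MAX_FACIN_EDGES,
    rank_by: str = "mask",
) -> FaCIN:
    """Build the FaCIN by admitting ranked edges that stay connected to the site.

    Edges are taken greedily in rank order; an edge detached from the site's
    component is skipped and revisited after a connector joins (the scan
    restarts from the top after every admission, so higher-ranked edges take
    precedence as soon as they become admissible).  If the computation graph
    holds fewer than ``max_edges`` edges, all of them are candidates.
    """
    if rank_by == "mask":
        ranked = [(i, j) for i, j, _, _ in explanation.edges]
    elif rank_by == "delta_v":
        def key(rec):
            i, j, score, dv = rec
            d = dv if np.isfinite(dv) else -np.inf
            return (-d, -score, abs(j - i), i, j)
        ranked = [(i, j) for i, j, _, _ in sorted(explanation.edges, key=key)]
    else:
        raise ValueError("rank_by must be 'mask' or 'delta_v'")

    site = explanation.center
    admitted: List[Tuple[int, int]] = []
    in_comp: Set[int] = {site}
    taken: Set[Tuple[int, int]] = set()
    progress = True
    while progress and len(admitted) < max_edges:
        progress = False
        for e in ranked:
            if e in taken:
                continue
            i, j = e
            if i in in_comp or j in in_comp:
                admitted.append(e)
                taken.add(e)
                in_comp.update(e)
                progress = True
                break  # restart from the top: rank priority on revisit

    nodes = sorted(in_comp)
    bs = graph.bins[0].bin_size if graph.bins else DEFAULT_BIN_SIZE
    fac = FaCIN(
        site=site,
        nodes=nodes,
        edges=admitted,
        lengths={e: abs(e[1] - e[0]) * bs for e in admitted},
        intensities={e: float(graph.edges.get((min(e), max(e)), np.nan)) for e in admitted},
        site_label=int(graph.labels[site]) if graph.labels is not None else None,
        chrom=graph.chrom,
        bin_size=bs,
    )
    classify_bottleneck(fac)
    return fac


def classify_bottleneck(facin: FaCIN) -> FaCIN:
    """Partition FaCIN members into neck and other neighbors/interactions.

    Neck neighbors are the nodes joined to the prediction site by a retained
    direct edge; the joining edges are the neck interactions.  All remaining
    nodes and edges are "other".
    """
    site = facin.site
    neck_edges = [e for e in facin.edges if site in e]
    neck_nodes = sorted({u for e in neck_edges for u in e if u != site})
    facin.neck_interactions = neck_edges
    facin.neck_neighbors = neck_nodes
    facin.other_interactions = [e for e in facin.edges if site not in e]
    facin.other_neighbors = sorted(set(facin.nodes) - set(neck_nodes) - {site})
    return facin


def _bfs_counts(adj: Dict[int, List[int]], source: int):
    """Shortest-path distances and path counts from `source`."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def betweenness_to_site(facin: FaCIN) -> Dict[int, float]:
    """Fraction of shortest source->site paths passing through each member.

    For node v: sum over sources s not in {v, site} of
    (number of shortest s->site paths through v) / (number of shortest
    s->site paths), with fractional counting over path multiplicity.
    """
    adj = facin.adjacency()
    site = facin.site
    d_site, c_site = _bfs_counts(adj, site)
    scores = {v: 0.0 for v in facin.nodes if v != site}
    for s in facin.nodes:
        if s == site or s not in d_site:
            continue
        d_s, c_s = _bfs_counts(adj, s)
        total = c_s[site]
        for v in scores:
            if v == s or v not in d_s or v not in d_site:
                continue
            if d_s[v] + d_site[v] == d_s[site]:
                scores[v] += c_s[v] * c_site[v] / total
    return scores


def facin_stats(facins: Sequence[FaCIN]) -> Dict:
    """Neck-interaction counts and length/intensity distributions by site class."""
    if len(facins) == 0:
        raise ValueError("at least one FaCIN required")
    neck_counts = Counter(len(f.neck_interactions) for f in facins)
    out = {
        "n_facins": len(facins),
        "neck_count_histogram": dict(sorted(neck_counts.items())),
        "mean_neck_interactions": float(np.mean([len(f.neck_interactions) for f in facins])),
    }
    for cls, name in ((1, "dsb"), (0, "non_dsb")):
        subset = [f for f in facins if f.site_label == cls]
        lengths = [f.lengths[e] for f in subset for e in f.neck_interactions]
        intens = [f.intensities[e] for f in subset for e in f.neck_interactions]
        out[f"{name}_neck_lengths_bp"] = lengths
        out[f"{name}_neck_intensities"] = intens
        out[f"{name}_mean_neck_length_bp"] = float(np.mean(lengths)) if lengths else float("nan")
        out[f"{name}_mean_neck_intensity"] = float(np.mean(intens)) if intens else float("nan")
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def facins_to_jsonl(facins: Iterable[FaCIN], path) -> None:
    with open(path, "w") as fh:
        for f in facins:
            rec = {
                "site": f.site,
                "chrom": f.chrom,
                "site_label": f.site_label,
                "bin_size": f.bin_size,
                "nodes": f.nodes,
                "edges": [list(e) for e in f.edges],
                "neck_neighbors": f.neck_neighbors,
                "neck_interactions": [list(e) for e in f.neck_interactions],
                "other_neighbors": f.other_neighbors,
                "other_interactions": [list(e) for e in f.other_interactions],
                "lengths": {f"{i},{j}": v for (i, j), v in f.lengths.items()},
                "intensities": {f"{i},{j}": v for (i, j), v in f.intensities.items()},
            }
            fh.write(json.dumps(rec) + "\n")


def facins_from_jsonl(path) -> List[FaCIN]:
    out = []
    with open(path) as fh:
        for line in fh:
            r = json.loads(line)
            def unkey(d):
                return {tuple(int(x) for x in k.split(",")): v for k, v in d.items()}
            out.append(FaCIN(
                site=r["site"], nodes=r["nodes"],
                edges=[tuple(e) for e in r["edges"]],
                neck_neighbors=r["neck_neighbors"],
                neck_interactions=[tuple(e) for e in r["neck_interactions"]],
                other_neighbors=r["other_neighbors"],
                other_interactions=[tuple(e) for e in r["other_interactions"]],
                lengths=unkey(r["lengths"]), intensities=unkey(r["intensities"]),
                site_label=r["site_label"], chrom=r["chrom"], bin_size=r["bin_size"],
            ))
    return out


def neck_interactions_table(facins: Sequence[FaCIN]) -> pd.DataFrame:
    """BEDPE-style table of neck interactions for genomic-context analyses."""
    rows = []
    for f in facins:
        for (i, j) in f.neck_interactions:
            a, b = min(i, j), max(i, j)
            rows.append({
                "chrom1": f.chrom, "start1": a * f.bin_size, "end1": (a + 1) * f.bin_size,
                "chrom2": f.chrom, "start2": b * f.bin_size, "end2": (b + 1) * f.bin_size,
                "site": f.site, "site_label": f.site_label,
                "intensity": f.intensities[(i, j)],
            })
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                                       "end2", "site", "site_label", "intensity"])
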