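"""Genome binning, feature tracks and Hi-C contact-graph assembly.

A chromosome is tiled into fixed-size bins (5 kb by default).  Each bin
carries a 1346-long feature vector — k-mer frequencies for k = 3, 4, 5
(4^3 + 4^4 + 4^5 = 1344 entries) plus CTCF and DNase peak densities — and a
binary DSB label.  Raw intrachromosomal contact counts between bins become
the weighted edges of an undirected per-chromosome graph; contacts below a
retention threshold (default 2) and self-contacts are dropped.

Coordinates are 0-based half-open (BED convention) throughout; bin index =
floor(start / bin_size).  K-mers are counted on the forward strand only and
windows containing N are skipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Bin",
    "ContactRecord",
    "ContactGraph",
    "bin_genome",
    "contacts_to_graph",
    "kmer_features",
    "kmer_feature_length",
    "signal_density",
    "label_bins",
    "downsample_contacts",
    "build_graph",
    "read_bed",
    "read_contacts",
    "write_contacts",
    "save_graph",
    "load_graph",
    "filter_chromosomes",
    "DEFAULT_BIN_SIZE",
    "DEFAULT_MIN_COUNT",
    "KMER_KS",
    "N_FEATURES",
]

DEFAULT_BIN_SIZE = 5000
DEFAULT_MIN_COUNT = 2
KMER_KS = (3, 4, 5)
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_feature_length(k_list: Sequence[int] = KMER_KS) -> int:
    return int(sum(4 ** k for k in k_list))


N_FEATURES = kmer_feature_length() + 2  # k-mer blocks + CTCF + DNase = 1346


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Bin:
    """A genome bin; the last bin of a chromosome may be partial."""

    chrom: str
    index: int
    start: int
    end: int
    bin_size: int = DEFAULT_BIN_SIZE

    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ContactRecord:
    bin_i: int
    bin_j: int
    count: int


@dataclass
class ContactGraph:
    """Undirected weighted contact graph for one chromosome.

    ``edges`` maps ordered bin-index pairs (i < j) to integer contact counts;
    ``features`` is an (n_bins, 1346) array and ``labels`` a 0/1 vector.
    """

    chrom: str
    bins: List[Bin]
    edges: Dict[Tuple[int, int], int] = field(default_factory=dict)
    features: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    @property
    def n_nodes(self) -> int:
        return len(self.bins)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for (i, j) in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, node: int) -> List[int]:
        out = []
        for (i, j) in self.edges:
            if i == node:
                out.append(j)
            elif j == node:
                out.append(i)
        return sorted(out)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from((i, j, w) for (i, j), w in self.edges.items())
        return g


# ---------------------------------------------------------------------------
# binning and labels
# ---------------------------------------------------------------------------

def bin_genome(chrom_sizes: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> List[Bin]:
    """Tile each chromosome with consecutive bins; the last bin is truncated."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: List[Bin] = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome size must be positive ({chrom}={size})")
        n = (size + bin_size - 1) // bin_size
        for i in range(n):
            start = i * bin_size
            bins.append(Bin(chrom, i, start, min(start + bin_size, size), bin_size))
    return bins


def label_bins(dsb_intervals: Iterable[GenomicInterval], bins: Sequence[Bin]) -> np.ndarray:
    """A bin is a DSB bin iff it overlaps at least one interval by >= 1 bp."""
    labels = np.zeros(len(bins), dtype=np.int64)
    by_chrom: Dict[str, List[Tuple[int, Bin]]] = {}
    for pos, b in enumerate(bins):
        by_chrom.setdefault(b.chrom, []).append((pos, b))
    for iv in dsb_intervals:
        for pos, b in by_chrom.get(iv.chrom, ()):
            if iv.start < b.end and b.start < iv.end:
                labels[pos] = 1
    return labels


def signal_density(peaks: Iterable[GenomicInterval], bin: Bin) -> float:
    """Fraction of the bin covered by the union of the peak intervals."""
    clipped = sorted(
        (max(p.start, bin.start), min(p.end, bin.end))
        for p in peaks
        if p.chrom == bin.chrom and p.start < bin.end and p.end > bin.start
    )
    covered, cur_start, cur_end = 0, None, None
    for s, e in clipped:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / (bin.end - bin.start)


# ---------------------------------------------------------------------------
# k-mer features
# ---------------------------------------------------------------------------

def kmer_features(sequence: str, k_list: Sequence[int] = KMER_KS) -> np.ndarray:
    """Concatenated k-mer frequency blocks, lexicographic k-mer order per k.

    Sliding windows containing N (or any non-ACGT symbol) are skipped.  Each
    k-block is normalized to sum to 1 when at least one valid window exists,
    and is all-zero otherwise.
    """
    seq = sequence.upper()
    codes = np.fromiter((_BASE_CODE.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))
    out = []
    for k in k_list:
        n_kmers = 4 ** k
        if len(codes) < k:
            out.append(np.zeros(n_kmers))
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            out.append(np.zeros(n_kmers))
            continue
        weights = 4 ** np.arange(k - 1, -1, -1)
        ids = windows[valid] @ weights
        counts = np.bincount(ids, minlength=n_kmers).astype(np.float64)
        out.append(counts / counts.sum())
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contacts_to_graph(
    records: Iterable[ContactRecord], min_count: int = DEFAULT_MIN_COUNT
) -> Dict[Tuple[int, int], int]:
    """Threshold, symmetrize and deduplicate raw contact records.

    Self-contacts are dropped; symmetric duplicates are merged keeping the
    larger count; only edges with count >= min_count are retained.
    """
    merged: Dict[Tuple[int, int], int] = {}
    for r in records:
        if r.count < 0:
            raise ValueError(f"negative contact count for pair ({r.bin_i},{r.bin_j})")
        if r.bin_i == r.bin_j:
            continue
        key = (min(r.bin_i, r.bin_j), max(r.bin_i, r.bin_j))
        prev = merged.get(key)
        if prev is None or r.count > prev:
            merged[key] = r.count
    return {k: c for k, c in merged.items() if c >= min_count}


def downsample_contacts(
    records: Sequence[ContactRecord], fraction: float, seed: int = 0
) -> List[ContactRecord]:
    """Binomial thinning: each contact retained independently with p=fraction."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(records)
    rng = np.random.default_rng(seed)
    counts = rng.binomial([r.count for r in records], fraction)
    return [
        ContactRecord(r.bin_i, r.bin_j, int(c)) for r, c in zip(records, counts)
    ]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_bed(path) -> List[GenomicInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2])
    return [GenomicInterval(str(c), int(s), int(e)) for c, s, e in df.itertuples(index=False)]


def read_contacts(path) -> List[ContactRecord]:
    """Tab-separated COO triples: bin_i, bin_j, raw count."""
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "count"])
    return [ContactRecord(int(i), int(j), int(c)) for i, j, c in df.itertuples(index=False)]


def write_contacts(records: Iterable[ContactRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.bin_i}\t{r.bin_j}\t{r.count}\n")


def filter_chromosomes(chroms: Iterable[str]) -> List[str]:
    """Keep autosomes and X; drop Y and anything non-canonical (e.g. chrM, scaffolds)."""
    kept = []
    for c in chroms:
        name = c[3:] if c.lower().startswith("chr") else c
        if name == "X" or name.isdigit():
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_graph(
    chrom: str,
    chrom_size: int,
    records: Iterable[ContactRecord],
    fasta=None,
    ctcf_peaks: Sequence[GenomicInterval] = (),
    dnase_peaks: Sequence[GenomicInterval] = (),
    dsb_intervals: Sequence[GenomicInterval] = (),
    bin_size: int = DEFAULT_BIN_SIZE,
    min_count: int = DEFAULT_MIN_COUNT,
) -> ContactGraph:
    """Assemble the per-chromosome contact graph with features and labels.

    ``fasta`` may be a pyfaidx.Fasta handle, a mapping chrom -> sequence
    string, or None (zero k-mer block for every bin).
    """
    bins = bin_genome({chrom: chrom_size}, bin_size)
    edges = contacts_to_graph(records, min_count)
    n = len(bins)
    bad = [p for p in edges if p[0] >= n or p[1] >= n or p[0] < 0]
    if bad:
        raise ValueError(f"contact records reference bins outside {chrom}: {bad[:3]}")

    seq = None
    if fasta is not None:
        seq = str(fasta[chrom][:]) if not isinstance(fasta, dict) else fasta[chrom]

    nk = kmer_feature_length()
    features = np.zeros((n, nk + 2))
    ctcf_on_chrom = [p for p in ctcf_peaks if p.chrom == chrom]
    dnase_on_chrom = [p for p in dnase_peaks if p.chrom == chrom]
    for idx, b in enumerate(bins):
        if seq is not None:
            features[idx, :nk] = kmer_features(seq[b.start : b.end])
        features[idx, nk] = signal_density(ctcf_on_chrom, b)
        features[idx, nk + 1] = signal_density(dnase_on_chrom, b)

    labels = label_bins(dsb_intervals, bins)
    return ContactGraph(chrom=chrom, bins=bins, edges=edges, features=features, labels=labels)


def save_graph(graph: ContactGraph, out_prefix) -> None:
    """Serialize as JSON (structure, labels) + .npy features alongside."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "chrom": graph.chrom,
        "bin_size": graph.bins[0].bin_size if graph.bins else DEFAULT_BIN_SIZE,
        "chrom_size": graph.bins[-1].end if graph.bins else 0,
        "labels": graph.labels.tolist() if graph.labels is not None else None,
        "edges": [[i, j, w] for (i, j), w in sorted(graph.edges.items())],
    }
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump(meta, fh)
    if graph.features is not None:
        np.save(f"{out_prefix}.features.npy", graph.features)


def load_graph(prefix) -> ContactGraph:
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    bins = bin_genome({meta["chrom"]: meta["chrom_size"]}, meta["bin_size"])
    features = None
    if Path(f"{prefix}.features.npy").exists():
        features = np.load(f"{prefix}.features.npy")
    labels = np.asarray(meta["labels"], dtype=np.int64) if meta["labels"] is not None else None
    edges = {(int(i), int(j)): int(w) for i, j, w in meta["edges"]}
    return ContactGraph(meta["chrom"], bins, edges, features, labels)
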