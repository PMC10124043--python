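"""Desk-scale synthetic fixtures: contact maps, tracks, sequences, labels.

The generator emulates the inputs of the DSB-prediction pipeline without any
download: per-chromosome contact maps with power-law distance decay, CTCF /
DNase peak tracks, random DNA sequence, and DSB labels produced by a planted
causal rule.  A subset of bins ("planted sites") each receives one boosted
long-range contact to a designated partner bin; a site's label is 1 iff its
partner's CTCF density exceeds a threshold theta, flipped with probability
epsilon.  The rule is mutual: each endpoint of a planted edge is a planted
site whose designated partner is the other endpoint, so the label of every
planted bin is carried by its 1-hop neck neighbor, not by the bin itself —
the structure the explanation pipeline must recover.

Every quantity is drawn from named, per-chromosome substreams of one seed,
so fixtures are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import (
    ContactGraph,
    ContactRecord,
    DEFAULT_BIN_SIZE,
    DEFAULT_MIN_COUNT,
    GenomicInterval,
    bin_genome,
    contacts_to_graph,
    kmer_features,
    kmer_feature_length,
    write_contacts,
)

__all__ = [
    "FixtureConfig",
    "Fixture",
    "planted_pairs",
    "planted_site_partners",
    "simulate_contact_map",
    "simulate_labels_and_features",
    "generate_fixture",
    "build_fixture_graphs",
    "write_fixture",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Distance decay follows expected count = base_intensity / d^gamma over bin
    separation d.  Planted edges receive counts of min_count + 1 +
    Poisson(boost * base_intensity), far above the decay expectation at their
    separation, so they always survive the retention threshold.
    """

    chroms: Tuple[str, ...] = ("chrA", "chrB")
    n_bins: int = 500
    bin_size: int = DEFAULT_BIN_SIZE
    gamma: float = 1.0
    base_intensity: float = 8.0
    planted_fraction: float = 0.18
    planted_count: Optional[int] = None  # overrides planted_fraction if set
    min_partner_distance: int = 50  # bins
    max_partner_distance: int = 150
    boost: float = 5.0
    theta: float = 0.2  # CTCF threshold of the causal rule
    epsilon: float = 0.05  # label-flip noise
    min_count: int = DEFAULT_MIN_COUNT
    n_tads: int = 8
    n_decoy_loops: int = 20
    enhancer_fraction: float = 0.1
    tss_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.epsilon < 0.5):
            raise ValueError("epsilon must be in [0, 0.5)")
        if self.n_bins < 20:
            raise ValueError("n_bins must be >= 20")

    def n_planted(self) -> int:
        if self.planted_count is not None:
            return self.planted_count
        return int(round(self.planted_fraction * self.n_bins))


@dataclass
class Fixture:
    """In-memory fixture: one entry per chromosome in every mapping."""

    config: FixtureConfig
    contacts: Dict[str, List[ContactRecord]]
    planted: Dict[str, List[Tuple[int, int]]]  # (site, partner) bin pairs
    ctcf: Dict[str, np.ndarray]
    dnase: Dict[str, np.ndarray]
    sequences: Dict[str, str]
    labels: Dict[str, np.ndarray]
    tads: List[GenomicInterval] = field(default_factory=list)
    loops: List[Tuple[str, int, int]] = field(default_factory=list)  # (chrom, bin_a, bin_b)
    enhancers: List[GenomicInterval] = field(default_factory=list)
    tss: List[Tuple[str, int]] = field(default_factory=list)


def _rng(config: FixtureConfig, chrom_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, chrom_idx, stream])


def planted_pairs(config: FixtureConfig, chrom_idx: int) -> List[Tuple[int, int]]:
    """Deterministic planted-edge assignment for one chromosome.

    Each pair (a, b) makes *both* endpoints planted sites, each with the
    other endpoint as its designated causal partner (the rule is mutual, as
    for two physically interacting loci).  Endpoints are disjoint across
    pairs; the separation is uniform in
    [min_partner_distance, max_partner_distance] bins.
    """
    rng = _rng(config, chrom_idx, 0)
    n = config.n_bins
    n_pairs = config.n_planted() // 2
    anchors = rng.choice(n, size=min(2 * n_pairs, n), replace=False)[:n_pairs]
    taken = set(int(s) for s in anchors)
    pairs: List[Tuple[int, int]] = []
    for s in anchors:
        s = int(s)
        lo, hi = config.min_partner_distance, config.max_partner_distance
        candidates = [
            p
            for d in range(lo, hi + 1)
            for p in (s - d, s + d)
            if 0 <= p < n and p not in taken
        ]
        if not candidates:
            continue
        p = int(candidates[rng.integers(len(candidates))])
        taken.add(p)
        pairs.append((s, p))
    return pairs


def planted_site_partners(config: FixtureConfig, chrom_idx: int) -> Dict[int, int]:
    """site -> designated causal partner, both directions of every planted pair."""
    out: Dict[int, int] = {}
    for a, b in planted_pairs(config, chrom_idx):
        out[a] = b
        out[b] = a
    return out


def simulate_contact_map(config: FixtureConfig) -> Tuple[Dict[str, List[ContactRecord]], Dict[str, List[Tuple[int, int]]]]:
    """Poisson contact counts with power-law decay plus boosted planted edges."""
    contacts: Dict[str, List[ContactRecord]] = {}
    planted: Dict[str, List[Tuple[int, int]]] = {}
    n = config.n_bins
    for ci, chrom in enumerate(config.chroms):
        rng = _rng(config, ci, 1)
        counts: Dict[Tuple[int, int], int] = {}
        for d in range(1, n):
            mean = config.base_intensity / (d ** config.gamma)
            draws = rng.poisson(mean, size=n - d)
            nz = np.nonzero(draws)[0]
            for i in nz:
                counts[(int(i), int(i) + d)] = int(draws[i])
        pairs = planted_pairs(config, ci)
        boost_counts = rng.poisson(config.boost * config.base_intensity, size=len(pairs))
        for (s, p), bc in zip(pairs, boost_counts):
            key = (min(s, p), max(s, p))
            counts[key] = config.min_count + 1 + int(bc)
        contacts[chrom] = [ContactRecord(i, j, c) for (i, j), c in sorted(counts.items())]
        planted[chrom] = pairs
    return contacts, planted


def simulate_labels_and_features(
    config: FixtureConfig,
    contact_records: Optional[Dict[str, List[ContactRecord]]] = None,
) -> Tuple[Dict[str, np.ndarray], Dict[str, np.ndarray], Dict[str, str], Dict[str, np.ndarray]]:
    """CTCF/DNase scalars, random DNA, and labels from the planted rule.

    label(site) = 1 iff ctcf[partner] > theta, flipped with probability
    epsilon; the noise acts on the causal rule, so non-planted bins stay
    non-DSB.  CTCF/DNase values are quantized to 1/bin_size so that
    peak-coverage round-trips through BED files are exact.
    """
    del contact_records  # labels depend on the planted rule, not the counts
    ctcf: Dict[str, np.ndarray] = {}
    dnase: Dict[str, np.ndarray] = {}
    seqs: Dict[str, str] = {}
    labels: Dict[str, np.ndarray] = {}
    n, bs = config.n_bins, config.bin_size
    for ci, chrom in enumerate(config.chroms):
        rng = _rng(config, ci, 2)
        ctcf[chrom] = np.round(rng.uniform(size=n) * bs) / bs
        dnase[chrom] = np.round(rng.uniform(size=n) * bs) / bs
        codes = rng.integers(0, 4, size=n * bs, dtype=np.uint8)
        seqs[chrom] = _ALPHABET[codes].tobytes().decode("ascii")
        y = np.zeros(n, dtype=np.int64)
        flips = rng.uniform(size=n) < config.epsilon
        for s, p in planted_site_partners(config, ci).items():
            y[s] = 1 if ctcf[chrom][p] > config.theta else 0
            if flips[s]:
                y[s] = 1 - y[s]
        labels[chrom] = y
    return ctcf, dnase, seqs, labels


def generate_fixture(config: FixtureConfig) -> Fixture:
    """Full in-memory fixture: contacts, tracks, sequences, labels, annotations."""
    contacts, planted = simulate_contact_map(config)
    ctcf, dnase, seqs, labels = simulate_labels_and_features(config)
    n, bs = config.n_bins, config.bin_size
    chrom_len = n * bs

    # TADs: equal tiles with a one-bin boundary gap
    tads: List[GenomicInterval] = []
    tad_span = chrom_len // config.n_tads
    for chrom in config.chroms:
        for t in range(config.n_tads):
            start = t * tad_span
            end = min(start + tad_span - bs, chrom_len)
            if end > start:
                tads.append(GenomicInterval(chrom, start, end))

    # loops: every planted edge plus random decoys
    loops: List[Tuple[str, int, int]] = []
    for ci, chrom in enumerate(config.chroms):
        for s, p in planted[chrom]:
            loops.append((chrom, min(s, p), max(s, p)))
        rng = _rng(config, ci, 3)
        for _ in range(config.n_decoy_loops):
            a = int(rng.integers(n - 60))
            b = a + int(rng.integers(20, 60))
            if b < n:
                loops.append((chrom, a, b))

    enhancers: List[GenomicInterval] = []
    tss: List[Tuple[str, int]] = []
    for ci, chrom in enumerate(config.chroms):
        rng = _rng(config, ci, 4)
        n_enh = int(round(config.enhancer_fraction * n))
        n_tss = int(round(config.tss_fraction * n))
        for b in sorted(rng.choice(n, size=n_enh, replace=False)):
            start = int(b) * bs + bs // 4
            enhancers.append(GenomicInterval(chrom, start, start + bs // 2))
        for b in sorted(rng.choice(n, size=n_tss, replace=False)):
            tss.append((chrom, int(b) * bs + bs // 2))

    return Fixture(
        config=config, contacts=contacts, planted=planted, ctcf=ctcf,
        dnase=dnase, sequences=seqs, labels=labels, tads=tads, loops=loops,
        enhancers=enhancers, tss=tss,
    )


def build_fixture_graphs(fixture: Fixture, with_sequence: bool = True) -> Dict[str, ContactGraph]:
    """Assemble per-chromosome contact graphs directly from fixture arrays."""
    cfg = fixture.config
    nk = kmer_feature_length()
    graphs: Dict[str, ContactGraph] = {}
    for chrom in cfg.chroms:
        bins = bin_genome({chrom: cfg.n_bins * cfg.bin_size}, cfg.bin_size)
        edges = contacts_to_graph(fixture.contacts[chrom], cfg.min_count)
        features = np.zeros((cfg.n_bins, nk + 2))
        if with_sequence:
            seq = fixture.sequences[chrom]
            for b in bins:
                features[b.index, :nk] = kmer_features(seq[b.start : b.end])
        features[:, nk] = fixture.ctcf[chrom]
        features[:, nk + 1] = fixture.dnase[chrom]
        graphs[chrom] = ContactGraph(
            chrom=chrom, bins=bins, edges=edges,
            features=features, labels=fixture.labels[chrom].copy(),
        )
    return graphs


def write_fixture(config: FixtureConfig, out_dir) -> Fixture:
    """Emit the fixture as standard text formats plus a ground-truth JSON.

    Layout: contacts_<chrom>.tsv, genome.fa, dsb.bed, ctcf.bed, dnase.bed,
    tads.bed, loops.bedpe, enhancers.bed, tss.bed, ground_truth.json.
    Byte-identical under a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = generate_fixture(config)
    n, bs = config.n_bins, config.bin_size

    for chrom in config.chroms:
        write_contacts(fx.contacts[chrom], out / f"contacts_{chrom}.tsv")

    with open(out / "genome.fa", "w") as fh:
        for chrom in config.chroms:
            fh.write(f">{chrom}\n")
            seq = fx.sequences[chrom]
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")

    def write_bed(path, rows):
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    dsb_rows = []
    for chrom in config.chroms:
        for b in np.nonzero(fx.labels[chrom])[0]:
            start = int(b) * bs
            dsb_rows.append((chrom, start + 2000, start + 3000))
    write_bed(out / "dsb.bed", dsb_rows)

    for name, track in (("ctcf", fx.ctcf), ("dnase", fx.dnase)):
        rows = []
        for chrom in config.chroms:
            for b, v in enumerate(track[chrom]):
                span = int(round(v * bs))
                if span > 0:
                    rows.append((chrom, b * bs, b * bs + span))
        write_bed(out / f"{name}.bed", rows)

    write_bed(out / "tads.bed", [(t.chrom, t.start, t.end) for t in fx.tads])
    write_bed(
        out / "loops.bedpe",
        [(c, a * bs, (a + 1) * bs, c, b * bs, (b + 1) * bs) for c, a, b in fx.loops],
    )
    write_bed(out / "enhancers.bed", [(e.chrom, e.start, e.end) for e in fx.enhancers])
    write_bed(out / "tss.bed", [(c, p, p + 1) for c, p in fx.tss])

    truth = {
        "config": asdict(config),
        "planted": {c: [[int(s), int(p)] for s, p in prs] for c, prs in fx.planted.items()},
        "labels": {c: fx.labels[c].tolist() for c in config.chroms},
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return fx
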