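"""Placing chromatin interactions in TAD / loop / enhancer-promoter context.

Neck interactions (bin pairs) are tested for containment in TADs, for
coinciding with loop anchors, and for joining enhancer and promoter bins,
against matched-random backgrounds that preserve the interaction length
distribution.  Enrichment uses the upper-tail hypergeometric test, and 2x2
association tables use the odds ratio with a Pearson chi-square statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import DEFAULT_BIN_SIZE, GenomicInterval

__all__ = [
    "Interaction",
    "Loop",
    "interaction_from_bins",
    "neck_in_tad",
    "neck_is_loop",
    "ep_loop_detect",
    "matched_random_interactions",
    "hypergeom_enrichment",
    "odds_ratio_chisq",
    "kmer_motif_overlap",
    "read_bedpe",
    "interactions_from_table",
    "context_report",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Interaction:
    """An intrachromosomal bin pair; length is measured midpoint to midpoint."""

    chrom: str
    bin_a: int
    bin_b: int
    bin_size: int = DEFAULT_BIN_SIZE
    intensity: float = float("nan")

    def __post_init__(self):
        if self.bin_a > self.bin_b:
            raise ValueError("bin_a must be <= bin_b")

    @property
    def start_a(self) -> int:
        return self.bin_a * self.bin_size

    @property
    def end_a(self) -> int:
        return (self.bin_a + 1) * self.bin_size

    @property
    def start_b(self) -> int:
        return self.bin_b * self.bin_size

    @property
    def end_b(self) -> int:
        return (self.bin_b + 1) * self.bin_size

    @property
    def midpoint_a(self) -> float:
        return (self.bin_a + 0.5) * self.bin_size

    @property
    def midpoint_b(self) -> float:
        return (self.bin_b + 0.5) * self.bin_size

    @property
    def length(self) -> int:
        return (self.bin_b - self.bin_a) * self.bin_size


@dataclass(frozen=True)
class Loop:
    """A loop specified by two ordered, non-overlapping anchors on one chromosome."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval

    def __post_init__(self):
        a, b = self.anchor1, self.anchor2
        if a.chrom != b.chrom:
            raise ValueError("loop anchors must be on one chromosome")
        if a.start > b.start:
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)
            a, b = b, a
        if b.start < a.end:
            raise ValueError("loop anchors must not overlap")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom


def interaction_from_bins(chrom: str, bin_a: int, bin_b: int,
                          bin_size: int = DEFAULT_BIN_SIZE,
                          intensity: float = float("nan")) -> Interaction:
    a, b = min(bin_a, bin_b), max(bin_a, bin_b)
    return Interaction(chrom, a, b, bin_size, intensity)


# ---------------------------------------------------------------------------
# containment predicates
# ---------------------------------------------------------------------------

def neck_in_tad(interaction: Interaction, tads: Sequence[GenomicInterval]) -> bool:
    """True iff the first bin's end and the second bin's start fall in one TAD.

    Containment is closed on the stated coordinates.
    """
    c1, c2 = interaction.end_a, interaction.start_b
    for t in tads:
        if t.chrom == interaction.chrom and t.start <= c1 <= t.end and t.start <= c2 <= t.end:
            return True
    return False


def neck_is_loop(interaction: Interaction, loops: Sequence[Loop]) -> bool:
    """True iff the bin midpoints fall in the two anchors of a single loop.

    Both anchor orientations are accepted (interactions are unordered).
    """
    ma, mb = interaction.midpoint_a, interaction.midpoint_b

    def inside(x, iv):
        return iv.start <= x <= iv.end

    for lp in loops:
        if lp.chrom != interaction.chrom:
            continue
        if (inside(ma, lp.anchor1) and inside(mb, lp.anchor2)) or (
            inside(ma, lp.anchor2) and inside(mb, lp.anchor1)
        ):
            return True
    return False


def ep_loop_detect(
    interactions: Sequence[Interaction],
    enhancers: Sequence[GenomicInterval],
    tss_list: Sequence[Tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
    promoter_flank: int = 2000,
) -> List[Interaction]:
    """Interactions joining an enhancer bin and a promoter bin (E-P loops).

    Promoters are the +/- `promoter_flank` bp windows around each TSS,
    clipped at zero.  A bin overlapping a promoter (enhancer) interval is a
    promoter (enhancer) node; an interaction with one node of each kind is
    an E-P loop, counted once regardless of orientation or double overlap.
    """
    promoters = [
        GenomicInterval(chrom, max(pos - promoter_flank, 0), pos + promoter_flank)
        for chrom, pos in tss_list
    ]

    def overlaps(chrom, start, end, ivs):
        return any(iv.chrom == chrom and iv.start < end and start < iv.end for iv in ivs)

    out = []
    for it in interactions:
        a_enh = overlaps(it.chrom, it.start_a, it.end_a, enhancers)
        b_enh = overlaps(it.chrom, it.start_b, it.end_b, enhancers)
        a_pro = overlaps(it.chrom, it.start_a, it.end_a, promoters)
        b_pro = overlaps(it.chrom, it.start_b, it.end_b, promoters)
        if (a_enh and b_pro) or (b_enh and a_pro):
            out.append(it)
    return out


# ---------------------------------------------------------------------------
# matched-random background
# ---------------------------------------------------------------------------

def matched_random_interactions(
    interactions: Sequence[Interaction],
    chrom_sizes: Mapping[str, int],
    n_sets: int = 10,
    seed: int = 0,
) -> List[List[Interaction]]:
    """Random placements preserving the exact interaction length multiset.

    Each artificial interaction lands uniformly over valid placements on a
    uniformly chosen chromosome that can host its length; interactions too
    long for every chromosome are skipped with a warning.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[List[Interaction]] = []
    for _ in range(n_sets):
        placed: List[Interaction] = []
        for it in interactions:
            span_bins = it.bin_b - it.bin_a
            hosts = [
                (c, size // it.bin_size)
                for c, size in chrom_sizes.items()
                if size // it.bin_size > span_bins
            ]
            if not hosts:
                warnings.warn(
                    f"interaction length {it.length} bp exceeds every chromosome; skipped"
                )
                continue
            chrom, n_bins = hosts[rng.integers(len(hosts))]
            a = int(rng.integers(n_bins - span_bins))
            placed.append(Interaction(chrom, a, a + span_bins, it.bin_size, it.intensity))
        out.append(placed)
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent hypergeometric counts k={k} n={n} K={K} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def odds_ratio_chisq(table) -> Tuple[float, float, float]:
    """(odds ratio, Pearson chi-square, p) for a 2x2 table.

    Haldane-Anscombe 0.5 correction is applied to the odds ratio when any
    cell is zero; the chi-square uses no continuity correction.
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    a, b, c, d = t.ravel()
    if (t == 0).any():
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsratio = (a * d) / (b * c)
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(oddsratio), float(chi2), float(p)


def kmer_motif_overlap(kmer: str, motif: str) -> int:
    """Longest common substring between a k-mer and a motif or its reverse complement."""
    if not kmer or not motif:
        raise ValueError("kmer and motif must be non-empty")
    kmer = kmer.upper()
    best = 0
    for m in (motif.upper(), motif.upper().translate(_COMPLEMENT)[::-1]):
        prev = [0] * (len(m) + 1)
        for i in range(1, len(kmer) + 1):
            cur = [0] * (len(m) + 1)
            for j in range(1, len(m) + 1):
                if kmer[i - 1] == m[j - 1]:
                    cur[j] = prev[j - 1] + 1
                    best = max(best, cur[j])
            prev = cur
    return best


# ---------------------------------------------------------------------------
# IO and report
# ---------------------------------------------------------------------------

def read_bedpe(path) -> List[Loop]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3, 4, 5])
    return [
        Loop(GenomicInterval(str(c1), int(s1), int(e1)),
             GenomicInterval(str(c2), int(s2), int(e2)))
        for c1, s1, e1, c2, s2, e2 in df.itertuples(index=False)
    ]


def interactions_from_table(df: pd.DataFrame) -> List[Interaction]:
    """BEDPE-style table (as written by facin_core) -> Interaction list."""
    out = []
    for row in df.itertuples(index=False):
        bs = row.end1 - row.start1
        out.append(Interaction(str(row.chrom1), row.start1 // bs, row.start2 // bs,
                               bs, getattr(row, "intensity", float("nan"))))
    return out


def context_report(
    necks: Sequence[Interaction],
    tads: Sequence[GenomicInterval],
    loops: Sequence[Loop],
    chrom_sizes: Mapping[str, int],
    enhancers: Sequence[GenomicInterval] = (),
    tss_list: Sequence[Tuple[str, int]] = (),
    population: Optional[Sequence[Interaction]] = None,
    n_random_sets: int = 10,
    seed: int = 0,
) -> Dict:
    """TAD/loop/E-P placement of neck interactions with random backgrounds.

    Hypergeometric enrichment draws the population from `population` (all
    retained graph interactions) when given, otherwise from the pooled
    matched-random sets.
    """
    if len(necks) == 0:
        raise ValueError("no neck interactions given")
    rand_sets = matched_random_interactions(necks, chrom_sizes, n_random_sets, seed)
    in_tad = sum(neck_in_tad(x, tads) for x in necks)
    is_loop = sum(neck_is_loop(x, loops) for x in necks)
    rand_tad = [sum(neck_in_tad(x, tads) for x in s) / max(len(s), 1) for s in rand_sets]
    rand_loop = [sum(neck_is_loop(x, loops) for x in s) / max(len(s), 1) for s in rand_sets]

    pool = list(population) if population is not None else [x for s in rand_sets for x in s]
    pool_tad = sum(neck_in_tad(x, tads) for x in pool)
    pool_loop = sum(neck_is_loop(x, loops) for x in pool)
    N = len(necks) + len(pool)
    report = {
        "n_necks": len(necks),
        "frac_in_tad": in_tad / len(necks),
        "frac_is_loop": is_loop / len(necks),
        "random_frac_in_tad": rand_tad,
        "random_frac_is_loop": rand_loop,
        "p_in_tad": hypergeom_enrichment(in_tad, len(necks), in_tad + pool_tad, N),
        "p_is_loop": hypergeom_enrichment(is_loop, len(necks), is_loop + pool_loop, N),
    }
    if enhancers or tss_list:
        report["n_ep_loops"] = len(ep_loop_detect(necks, enhancers, list(tss_list)))
    return report
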