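"""End-to-end planted-fixture benchmark of the whole pipeline.

Runs the complete study on the synthetic conditions: generate the two-
chromosome fixture, train the classifier on one chromosome, evaluate on the
held-out one, explain every planted site there, extract FaCINs, and compute
the downstream structural statistics (planted-edge recovery, neck-vs-other
betweenness, motif enrichment against the random-walk null, TAD/loop
context).  A calibration arm re-runs training on label-free noise (random
labels, four chromosomes) and measures the self-enrichment of random
interactions against their own matched background.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .explainer import ExplainerConfig, SitePredictor, explain
from .facin_core import betweenness_to_site, extract_facin, neck_interactions_table
from .genomic_context import context_report, interactions_from_table, neck_in_tad
from .graph_model import ModelConfig, evaluate, train
from .structure_motifs import canonical_form, count_motifs, generate_null, motif_enrichment
from .synthetic_data import (
    FixtureConfig,
    build_fixture_graphs,
    generate_fixture,
    planted_site_partners,
)

__all__ = ["run_planted_benchmark", "run_null_calibration"]

CASCADE = canonical_form([(0, 1), (1, 2)], 0)
BIFURCATE = canonical_form([(0, 1), (1, 2), (1, 3)], 0)


def run_planted_benchmark(
    seed: int = 1,
    fixture_config: Optional[FixtureConfig] = None,
    model_config: Optional[ModelConfig] = None,
    explainer_config: Optional[ExplainerConfig] = None,
) -> Dict:
    """Train, explain and analyze the planted fixture; held-out throughout."""
    cfg = fixture_config or FixtureConfig(seed=seed)
    fx = generate_fixture(cfg)
    graphs = build_fixture_graphs(fx)
    train_chrom, test_chrom = cfg.chroms[0], cfg.chroms[1]

    mc = model_config or ModelConfig(seed=seed)
    model = train([graphs[train_chrom]], mc)
    g_test = graphs[test_chrom]
    probs, auroc = evaluate(model, g_test)

    sp = planted_site_partners(cfg, cfg.chroms.index(test_chrom))
    ec = explainer_config or ExplainerConfig(seed=seed)
    predictor = SitePredictor(model, g_test)
    facins = []
    recovered = 0
    for site, partner in sorted(sp.items()):
        e = explain(model, g_test, site, ec, predictor=predictor)
        f = extract_facin(e, g_test)
        facins.append(f)
        key = (min(site, partner), max(site, partner))
        if key in {(min(a, b), max(a, b)) for a, b in f.neck_interactions}:
            recovered += 1

    # bottleneck signature: neck members mediate paths to the site
    neck_bc, other_bc = [], []
    for f in facins:
        bc = betweenness_to_site(f)
        neck_bc.extend(bc[v] for v in f.neck_neighbors)
        other_bc.extend(bc[v] for v in f.other_neighbors)

    # motif enrichment against the random-walk null
    obs_classes = count_motifs(facins)
    null_subs = [s for s in generate_null(g_test, [f.site for f in facins], seed=seed)
                 if s.edges]
    null_classes = count_motifs(null_subs)
    enrich = motif_enrichment(obs_classes, null_classes).set_index("motif")
    n_fac = sum(c.count for c in obs_classes)
    cascade_bifurcate_frac = sum(
        c.count for c in obs_classes if c.label in (CASCADE, BIFURCATE)) / n_fac
    top_label = obs_classes[0].label
    top_motif_p = float(enrich.loc[top_label, "p_value"])

    # genomic context of neck interactions
    necks = interactions_from_table(neck_interactions_table(facins))
    chrom_sizes = {c: cfg.n_bins * cfg.bin_size for c in (test_chrom,)}
    tads = [t for t in fx.tads if t.chrom == test_chrom]
    from .genomic_context import Loop
    from .genome_io import GenomicInterval

    loops = [
        Loop(GenomicInterval(c, a * cfg.bin_size, (a + 1) * cfg.bin_size),
             GenomicInterval(c, b * cfg.bin_size, (b + 1) * cfg.bin_size))
        for c, a, b in fx.loops if c == test_chrom
    ]
    ctx = context_report(necks, tads, loops, chrom_sizes, seed=seed)

    return {
        "fixture": cfg,
        "model": model,
        "facins": facins,
        "heldout_auroc": float(auroc),
        "n_planted_sites": len(sp),
        "neck_recovery_rate": recovered / len(sp),
        "mean_neck_betweenness": float(np.mean(neck_bc)) if neck_bc else 0.0,
        "mean_other_betweenness": float(np.mean(other_bc)) if other_bc else 0.0,
        "mean_neck_interactions_per_site": float(
            np.mean([len(f.neck_interactions) for f in facins])),
        "cascade_bifurcate_fraction": float(cascade_bifurcate_frac),
        "top_motif_p_value": top_motif_p,
        "neck_frac_in_tad": float(ctx["frac_in_tad"]),
        "neck_frac_is_loop": float(ctx["frac_is_loop"]),
        "random_frac_is_loop_mean": float(np.mean(ctx["random_frac_is_loop"])),
        "p_neck_is_loop": float(ctx["p_is_loop"]),
    }


def run_null_calibration(seed: int = 1, epochs: int = 150) -> Dict:
    """No-signal controls: random labels and self-matched random interactions.

    Labels drawn independently of graph and features (2000 bins over four
    chromosomes, one held out) should give chance-level AUROC; random
    interactions tested against their own matched-length background should
    show no TAD enrichment (ratio ~ 1).
    """
    cfg = FixtureConfig(chroms=("n1", "n2", "n3", "n4"), seed=seed + 1000)
    fx = generate_fixture(cfg)
    graphs = build_fixture_graphs(fx)
    rng = np.random.default_rng(seed + 2000)
    for c in cfg.chroms:
        graphs[c].labels = rng.binomial(1, 0.15, cfg.n_bins).astype(np.int64)
    mc = ModelConfig(seed=seed, epochs=epochs)
    model = train([graphs[c] for c in cfg.chroms[:3]], mc)
    _, null_auroc = evaluate(model, graphs[cfg.chroms[3]])

    # self-calibration of the matched-random machinery: the probe set is
    # itself a random placement, so its "enrichment" must be flat
    chrom_sizes = {c: cfg.n_bins * cfg.bin_size for c in cfg.chroms[:1]}
    tads = [t for t in fx.tads if t.chrom == cfg.chroms[0]]
    prng = np.random.default_rng(seed + 3000)
    from .genomic_context import interaction_from_bins, matched_random_interactions

    probe = []
    for _ in range(200):
        d = int(prng.integers(5, 150))
        a = int(prng.integers(cfg.n_bins - d))
        probe.append(interaction_from_bins(cfg.chroms[0], a, a + d, cfg.bin_size))

    background = matched_random_interactions(probe, chrom_sizes, n_sets=10,
                                             seed=seed + 4000)
    frac_probe = np.mean([neck_in_tad(x, tads) for x in probe])
    frac_bg = np.mean([[neck_in_tad(x, tads) for x in s] for s in background])
    ratio = float(frac_probe / frac_bg) if frac_bg > 0 else float("nan")
    return {
        "null_auroc": float(null_auroc),
        "self_enrichment_ratio": ratio,
    }
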