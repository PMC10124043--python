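import numpy as np
import pytest

from facin import (
    ContactGraph,
    FixtureConfig,
    ModelConfig,
    bin_genome,
    build_fixture_graphs,
    generate_fixture,
    train,
)
from facin.genome_io import kmer_feature_length

N_FEAT = kmer_feature_length() + 2


def random_graph(n_nodes=8, edge_prob=0.4, seed=0, chrom="chrT") -> ContactGraph:
    """Small random contact graph with random features and labels."""
    rng = np.random.default_rng(seed)
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges[(i, j)] = int(rng.integers(2, 20))
    bins = bin_genome({chrom: n_nodes * 5000}, 5000)
    features = rng.random((n_nodes, N_FEAT))
    labels = rng.integers(0, 2, n_nodes)
    return ContactGraph(chrom=chrom, bins=bins, edges=edges,
                        features=features, labels=labels)


def path_graph(n_nodes, chrom="chrP", seed=0) -> ContactGraph:
    rng = np.random.default_rng(seed)
    edges = {(i, i + 1): int(rng.integers(2, 10)) for i in range(n_nodes - 1)}
    bins = bin_genome({chrom: n_nodes * 5000}, 5000)
    return ContactGraph(chrom=chrom, bins=bins, edges=edges,
                        features=rng.random((n_nodes, N_FEAT)),
                        labels=rng.integers(0, 2, n_nodes))


@pytest.fixture(scope="session")
def small_fixture():
    """Desk-scale planted fixture: 2 chromosomes x 150 bins."""
    cfg = FixtureConfig(chroms=("c1", "c2"), n_bins=150, seed=7,
                        min_partner_distance=30, max_partner_distance=80)
    fx = generate_fixture(cfg)
    return cfg, fx, build_fixture_graphs(fx)


@pytest.fixture(scope="session")
def small_trained(small_fixture):
    """Model trained on the first chromosome of the small fixture."""
    cfg, fx, graphs = small_fixture
    mc = ModelConfig(epochs=250, seed=0)
    model = train([graphs["c1"]], mc)
    return model, cfg, fx, graphs
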