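"""Count FaCIN topologies and test enrichment against a random-walk null.

Builds rooted topologies directly (a cascade-heavy population) and compares
them with degree-matched random-walk subgraphs on a background graph.
"""

import numpy as np

from facin import FixtureConfig, build_fixture_graphs, generate_fixture
from facin.structure_motifs import (RootedSubgraph, count_motifs,
                                    generate_null, motif_enrichment)

cfg = FixtureConfig(chroms=("c1",), n_bins=200, seed=4,
                    min_partner_distance=30, max_partner_distance=80)
graph = build_fixture_graphs(generate_fixture(cfg), with_sequence=False)["c1"]

rng = np.random.default_rng(0)
observed = []
for root in rng.choice(150, size=60, replace=False):
    root = int(root)
    if rng.random() < 0.7:  # cascade: root - a - b
        observed.append(RootedSubgraph(root, [(root, root + 1), (root + 1, root + 2)]))
    else:  # bifurcate: root - a, a - b, a - c
        observed.append(RootedSubgraph(root, [(root, root + 1), (root + 1, root + 2),
                                              (root + 1, root + 3)]))

null = count_motifs([s for s in generate_null(graph, [s.root for s in observed], seed=1)
                     if s.edges])
report = motif_enrichment(count_motifs(observed), null)
print(report[["observed", "observed_freq", "null_count", "ratio", "p_value"]]
      .head(3).to_string())
# A motif with ratio >> 1 and small p occurs far more often among the
# observed topologies than among size- and radius-matched random walks.
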