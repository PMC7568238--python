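"""Distance-sweep enrichment: how close are DE genes to binding sites?

Extends every peak by ±d over a grid of distances, captures genes by TSS
containment, and tests each cluster for hypergeometric over-representation
among the captured genes.
"""

import numpy as np

from regdomain import DEFAULT_DISTANCES, SimConfig, distance_sweep
from regdomain.simulate import simulate_annotation, simulate_clusters, simulate_peaks_planted

cfg = SimConfig(seed=42)
rng = np.random.default_rng(cfg.seed)
sizes, genes = simulate_annotation(cfg, rng)
clusters = simulate_clusters(cfg, genes, rng)
peaks, _ = simulate_peaks_planted(cfg, genes, clusters, rng)

table = distance_sweep(peaks, genes, list(clusters.values()), DEFAULT_DISTANCES, sizes)
cols = ["cluster", "distance_bp", "n", "k", "prop_cluster", "prop_universe", "neg_log10_p", "fold"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Read prop_cluster vs prop_universe as the proportion-within-distance curves:
# the planted liver_up cluster sits far above the all-genes background at
# every distance (large -log10 p), the unplanted liver_down cluster tracks
# the background (p near 1), and the 3,000-gene global_ko_up cluster shows a
# weaker, longer-range association that peaks around its 50 kbp plant scale.
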