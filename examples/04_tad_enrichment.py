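"""Domain-level association: do DE genes share a TAD with a binding site?

Genes are assigned to the domain containing their TSS; domains overlapping a
peak are flagged; the cluster is tested for over-representation among genes
in flagged domains, against the domain-assigned universe.
"""

import numpy as np

from regdomain import DomainMap, SimConfig, domain_enrichment
from regdomain.simulate import (
    simulate_annotation,
    simulate_clusters,
    simulate_domains,
    simulate_peaks_planted,
)

cfg = SimConfig(seed=42)
rng = np.random.default_rng(cfg.seed)
sizes, genes = simulate_annotation(cfg, rng)
clusters = simulate_clusters(cfg, genes, rng)
peaks, _ = simulate_peaks_planted(cfg, genes, clusters, rng)
domains = DomainMap(simulate_domains(cfg, rng))

print(f"{len(domains):,} domains (~{cfg.chrom_length_bp // cfg.n_domains_per_chrom // 1000} kb each)")
for name in ("liver_up", "liver_down"):
    de = domain_enrichment(peaks, genes, clusters[name], domains)
    print(
        f"{name}: {de.pct_cluster:.1f}% of cluster genes share a domain with a peak "
        f"vs {de.pct_all:.1f}% of all genes  (-log10 p = {de.result.neg_log10_p:.2f})"
    )
# The planted cluster concentrates in peak-bearing domains well beyond the
# genome-wide percentage; the unplanted cluster matches it (p near 1).
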