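# regdomain

Integrating a transcription factor's **cistrome** (its genome-wide binding
sites from ChIP-seq) with its **transcriptome** response (differentially
expressed gene clusters from RNA-seq) is a recurring analysis in regulatory
genomics: are the genes that respond to perturbing the factor actually close
to — or in the same chromatin domain as — its binding sites?

`regdomain` is a tested, reusable implementation of that analysis for
nuclear-receptor-style studies (the motivating case is a circadian repressor
in mouse liver). It provides:

- **Consensus peak derivation** — anchored interval intersection
  (bedtools `-u` semantics: report anchor-set peaks overlapping ≥ 1 bp with
  every comparison set), for peak calls made against multiple backgrounds.
- **Distance-sweep enrichment** — extend peaks by ±d, capture genes by TSS
  containment, and test a DE cluster for over-representation with a
  hypergeometric upper tail, across a grid of distances (default
  100 bp – 100 kbp), yielding proportion-within-distance curves and a
  −log10 p profile.
- **TAD/subTAD-bounded analysis** — clip regulatory windows at domain
  boundaries, and test whether DE genes share a domain with a binding site.
- **Three-way cistrome partitioning** — Venn-style anchored overlap
  categories across three peak sets.
- **Motif fold-enrichment** — two-strand PWM scanning of target vs matched
  background regions: FE = (% targets containing the motif) / (% background
  containing it), with a hypergeometric p on the presence/absence table.
- **A synthetic-study generator** — linked annotation, peaks, clusters,
  domains and sequences with *planted, recoverable* structure, so every
  stage is testable without sequencing data.

## The core statistic

For a gene universe of size $N$ containing a DE cluster of size $K$: extend
each peak $[s, e)$ to $[s-d,\; e+d)$ (clipped at chromosome bounds, or at the
boundaries of the TAD containing the peak), and let $n$ be the number of
genes whose TSS falls inside at least one window, $k$ of them from the
cluster. Under the null that capture is blind to cluster membership,

$$P = \Pr(X \ge k), \qquad X \sim \mathrm{Hypergeom}(N, K, n),$$

computed in log space so extreme significance keeps a finite $-\log_{10}P$.
Reported alongside: $\mathrm{fold} = (k/K)/(n/N)$ and the proportions $k/K$
(cluster within distance $d$) and $n/N$ (all genes). Coordinates are 0-based
half-open throughout; a gene's position is its strand-resolved TSS
(`start` on `+`, `end − 1` on `−`).

## Worked example

```python
import numpy as np
from regdomain import SimConfig, DEFAULT_DISTANCES, distance_sweep
from regdomain.simulate import simulate_annotation, simulate_clusters, simulate_peaks_planted

cfg = SimConfig(seed=42)          # 20,000 genes, 8,660 peaks, planted clusters
rng = np.random.default_rng(cfg.seed)
sizes, genes = simulate_annotation(cfg, rng)
clusters = simulate_clusters(cfg, genes, rng)
peaks, truth = simulate_peaks_planted(cfg, genes, clusters, rng)
table = distance_sweep(peaks, genes, [clusters["liver_up"]], DEFAULT_DISTANCES, sizes)
cols = ["distance_bp", "n", "k", "prop_cluster", "prop_universe", "neg_log10_p"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

prints (seed 42; rows excerpted):

```
 distance_bp     n    k  prop_cluster  prop_universe  neg_log10_p
         100   281    8         0.057          0.014        3.081
        5000  2975   79         0.564          0.149       29.399
       50000 10684  133         0.950          0.534       27.405
      100000 14231  136         0.971          0.712       15.112
```

56.4% of the planted 140-gene cluster lies within 5 kbp of a peak versus
14.9% of all 20,000 genes — the planted 55%/15% contrast recovered to
binomial precision, with overwhelming significance — while an unplanted
cluster of the same study tracks the background (p ≈ 1 at every distance).
The `examples/` directory has one short script per capability (simulation,
sweep, consensus/Venn, TAD enrichment, motif enrichment).

A CLI mirrors the library for shell use:

```sh
regdomain simulate -o fixture/
regdomain sweep --peaks fixture/peaks.bed --genes fixture/genes.bed \
    --cluster fixture/clusters/liver_up.txt --chrom-sizes fixture/chrom.sizes -o sweep.tsv
regdomain run --config run.yaml --reproducible -o reports/
```

Every report carries a provenance header (tool version, config hash, seed,
anchor direction, universe size); `--reproducible` makes reruns
byte-identical.

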