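# Methods

## Scope and model

`regdomain` analyses the relationship between a transcription factor's
binding sites (peaks) and differentially expressed (DE) gene clusters. All
coordinates are 0-based half-open; every containment and overlap test is
start-inclusive, end-exclusive, so book-ended intervals never overlap. A
gene is represented by its strand-resolved TSS only (`start` on `+`,
`end − 1` on `−`): the analysis asks whether *TSSs* fall inside regulatory
windows, not whether gene bodies overlap them. Chromosome names are taken
verbatim; disjoint naming between files (e.g. `chr1` vs `1`) is a hard
error, because the silent alternative is an empty, wrong result.

### Distance-sweep enrichment

For extension distance d, each peak [s, e) becomes the window
[max(0, s−d), min(L, e+d)). Windows are **not** merged; capture
deduplicates at the gene level, which is equivalent for counting. With
universe size N, cluster size K, captured genes n, captured cluster genes k,
the p-value is the hypergeometric upper tail P(X ≥ k), the only direction
consistent with testing enrichment. The gene universe is the whole supplied
gene table, including genes on chromosomes without peaks ("all genes in the
genome" background). No multiple-testing correction is applied to the
headline values, matching how such distance profiles are plotted; a
Bonferroni-across-the-grid column is emitted additionally for users who want
it. Capture sets are nested in d, so n(d) and k(d) are non-decreasing — a
property the tests assert on every run.

Numerics: tails are summed in log space (gammaln + logsumexp). P(X ≥ k) is
exactly 1.0 for k at or below the lower support bound (in particular k = 0);
probabilities below the double floor report a finite −log10 p from the
log-space sum rather than 0. Relative accuracy is verified against exact
integer enumeration over the full lattice N ≤ 60 at < 1e−10. The fold
(k/K)/(n/N) is reported as NaN when n = 0; no finite value is fabricated.

### Domain-bounded windows and domain-level enrichment

A domain map (TADs or subTADs) must be non-overlapping — overlap is a load
error, and TAD/subTAD maps are handled as two separate maps, because "same
domain" is ill-posed under overlap. For domain-clipped sweeps a peak belongs
to the domain containing its **midpoint**; its window is intersected with
that domain, and peaks whose midpoint lies in no domain are excluded (and
counted in the log). The boundary-spanning-peak rule had to be chosen here;
midpoint assignment is deterministic and unambiguous.

The domain-level test restricts the universe to genes assigned to *some*
domain: a gene outside every TAD cannot share a TAD with a peak, and keeping
such genes in the background would inflate enrichment. The "percentage of
all genes" comparison uses the same restricted universe, and the restriction
is recorded in output metadata. This restriction was a genuinely open design
point; the alternative (whole-table universe) is not offered, to keep the
statistic's null coherent. With one whole-chromosome domain per chromosome
the domain test reproduces the d → ∞ sweep restricted to peak-bearing
chromosomes exactly — a consistency limit asserted in the tests.

### Consensus and overlap partitioning

Anchored intersection reports anchor-set intervals, with their original
coordinates, overlapping ≥ 1 bp of the query set (bedtools `-u` semantics;
cross-checked against bedtools in the tests). Anchored overlap is
asymmetric, so the anchor set is a required, logged choice: consensus counts
are anchor-set interval counts, and the three-way partition reports all
per-set category counts (each set's four categories sum exactly to its
size). No merging of book-ended or overlapping intervals is performed before
intersection; inputs are used as called. Overlap fraction thresholds beyond
≥ 1 bp are out of scope in this version.

### Motif fold-enrichment

A PWM is an L×4 probability matrix built from a JASPAR-style count matrix:
counts are normalised per position, then a 0.01 pseudocount is added and
renormalised, so zero counts score finitely. Scores are
Σ log2(p_i(base)/bg(base)), maximised over both strands (via the
reverse-complemented matrix) and all offsets; positions reading `N`
contribute the per-position minimum. A region *contains* the motif when its
best window reaches the threshold — presence/absence, not hit counts —
defaulting to 80% of the maximum attainable score (overridable). Fold
enrichment is pct_target / pct_background; significance is a hypergeometric
upper tail on the pooled presence/absence table (N = |T|+|B|, K = |T|,
n = total hits, k = target hits). This p-value is a deliberate, documented
simplification: published motif-discovery suites use their own internal
statistics and thresholds, so only the fold formula — not any particular
published fold value — is reproduced here. FE is NaN when the background
percentage is 0 with target hits present; with no hits anywhere FE = 1 is
implied and the degenerate case is logged.

## The synthetic-study generator

The generator's job is to emit data in which the analysis's assumptions hold
*exactly*, with known ground truth, at the scale the analyses target:
20,000 genes, 8,660 peaks (200–800 bp wide), a 140-gene planted "up" cluster
(55% within 5 kbp vs a 15% all-genes background; 87% within 50 kbp), an
82-gene unplanted "down" cluster (140 + 82 = 222 DE genes, the
liver-targeted scale), and a 3,000-gene (15%-of-genome) cluster with weaker,
longer-range planting (55% within 50 kbp) emulating a global-knockout
regime.

**Genome size.** Five chromosomes of 180 Mbp. At this scale the planted
construction below reproduces the 15%/55% contrast at 5 kbp exactly and
yields ≈ 50% background within 50 kbp. A substantially smaller genome cannot
host these conditions at all: ~3,000 peaks planted within 5 kbp of marked
genes already place ±5 kbp windows over >10% of a 250 Mb genome before any
further peaks exist, so the 15% background at 5 kbp pins the genome to
roughly this (mouse-chromosome) scale.

**Planting construction.** Capture structure is decided per gene, then
realised geometrically:

1. Every gene draws a *tier*: captured within the calibration distance
   (5 kbp), captured only within a longer plant distance (50 kbp tiers for
   the far-planted clusters), or unplanted. Cluster genes use their
   cluster's probabilities; remaining genes use a background rate derated so
   the **genome-wide expected proportion** within 5 kbp equals 15% (the
   published background is a proportion of all genes, so the planted
   cluster's contribution is absorbed by the rest).
2. Each planted gene receives one peak whose extended window at its tier
   distance contains its TSS; far-tier peaks are placed so they do *not*
   capture their own gene at 5 kbp.
3. **Every** peak — planted or filler — is placed so that its ±5 kbp window
   contains no TSS of a gene outside the 5 kbp tier. Capture at 5 kbp
   therefore equals the Bernoulli tier draw exactly, and recovered
   proportions are binomial around the planted rates. The rare gene whose
   peak cannot be placed (squeezed between close unplanted neighbours)
   swaps planted status with a random unplanted gene of its group, keeping
   the planted count.
4. Leftover "desert" peaks are scattered at hotspots within ±25 kbp of
   planted peaks, mimicking the locus-level clustering of real cistromes and
   keeping longer-range capture from saturating.

Capture at 5 kbp is exact by construction; capture at 50 kbp is *emergent*
(planted far tiers plus ambient coverage), so the 87%/~40–55% long-range
numbers are approximate emulation, not calibration. Exact two-distance
calibration is geometrically impossible at any realistic gene density:
±50 kbp avoidance zones around unplanted genes would cover the entire
genome.

**Other components.** TSSs are uniform with random strands (KS-checked in
the tests); domains are random non-overlapping partitions, 800 per
chromosome (~225 kb, subTAD scale) by default so the domain partition is
informative relative to binding-site spacing, with an optional inter-domain
gap fraction; region sequences are i.i.d. from the PWM background with
motif instances sampled column-wise from the PWM planted at configured
rates (60% targets / 10% background by default) at uniform offset and
strand. The bundled `RORE_like_synthetic` PWM is a synthetic stand-in — an
AGGTCA-hexamer core with an A/T-rich flank — not a database matrix. One
seeded NumPy stream drives all draws in a fixed order; identical
(config, seed) gives byte-identical fixtures.

**What the generator does not emulate.** Gene clustering (real TSSs are
heavily clustered; here uniform), peak-width/signal correlation, one peak
regulating several genes by design, isoform-level TSS ambiguity, and
realistic sequence composition (no repeats, no GC structure). Passing the
recovery tests therefore shows the *statistics* behave as designed under
their own assumptions, not that any particular biological dataset would
yield particular values.

## Test and problem sizes

The property suite runs the oracle comparisons at the sizes that make them
exhaustive or statistically sharp while staying desk-scale: the full
hypergeometric lattice at N ≤ 60; 200 random interval instances up to 1,000
intervals against all-pairs scans; 20 seeds of the full default study for
planted-signal recovery; 200 seeds for the null-calibration KS check
(performed at the 5 kbp calibration distance with a null cluster drawn
uniformly from the whole universe — uniform sampling of the cluster is
precisely the exchangeability the hypergeometric null assumes); 20 seeds of
500 + 500 motif regions. The acceptance script reruns the full default-scale
study end to end from a single seed.

## Known limitations

- One TSS per gene is required; multi-isoform genes must be pre-resolved
  upstream (the tool does not guess a representative transcript).
- No assembly liftover and no GTF/GFF parsing; inputs must share an
  assembly and arrive as BED-like tables.
- Anchored counts depend on the anchor; there is no symmetric
  (merged-locus) overlap mode in this version.
- The motif p-value is the package's own presence/absence hypergeometric,
  not comparable to p-values from motif-discovery suites.
- Significance of interval overlaps themselves (Jaccard/Fisher on genome
  bins) and nearest-gene assignment are out of scope.
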