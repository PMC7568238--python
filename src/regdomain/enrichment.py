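"""Distance-sweep enrichment of gene clusters near binding sites.

The core procedure: extend every peak by ±d bp (optionally clipped to the
chromatin domain containing the peak), collect all genes whose TSS falls
inside any extended window, and test whether a differentially-expressed gene
cluster is over-represented among the captured genes with a hypergeometric
upper tail against the whole gene universe.  Repeating over a grid of
distances yields the proportion-within-distance curves and the -log10 p
enrichment profile.

Windows from different peaks are not merged before capture; capture
deduplicates at the gene level, which is equivalent for counting.  The gene
universe is the full supplied gene table — genes on chromosomes without any
peak stay in the universe, matching an "all genes in the genome" background.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .domains import DomainMap
from .genome import ChromSizes, GeneCluster, GeneRecord, GenomicInterval
from .stats import EnrichmentResult

log = logging.getLogger(__name__)

#: Default distance grid, spanning 100 bp to 100 kbp.
DEFAULT_DISTANCES: tuple[int, ...] = (100, 500, 1000, 5000, 10000, 50000, 100000)

#: Exact column order of the sweep report.
SWEEP_COLUMNS = [
    "cluster",
    "distance_bp",
    "N",
    "K",
    "n",
    "k",
    "p_upper",
    "neg_log10_p",
    "fold",
    "prop_cluster",
    "prop_universe",
]


def extend_peaks(
    peaks: Sequence[GenomicInterval],
    d: int,
    chrom_sizes: ChromSizes,
    domains: DomainMap | None = None,
) -> list[GenomicInterval]:
    """Extend each peak [s, e) to [max(0, s-d), min(L, e+d)).

    With a domain map, each peak is assigned to the domain containing its
    midpoint and the extended window is clipped to that domain; peaks whose
    midpoint lies in no domain are excluded (their count is logged).  Output
    order follows input order.
    """
    if d < 0:
        raise ValueError(f"extension distance must be >= 0, got {d}")
    windows: list[GenomicInterval] = []
    n_excluded = 0
    for peak in peaks:
        length = chrom_sizes.require(peak.chrom)
        if peak.end > length:
            raise ValueError(
                f"peak {peak.chrom}:{peak.start}-{peak.end} exceeds chromosome length {length}"
            )
        start = max(0, peak.start - d)
        end = min(length, peak.end + d)
        if domains is not None:
            domain = domains.domain_at(peak.chrom, peak.midpoint)
            if domain is None:
                n_excluded += 1
                continue
            start = max(start, domain.start)
            end = min(end, domain.end)
            if end <= start:  # cannot happen: midpoint of the peak is inside the domain
                n_excluded += 1
                continue
        windows.append(GenomicInterval(peak.chrom, start, end, name=peak.name))
    if n_excluded:
        log.info("extend_peaks: excluded %d peaks with midpoint outside every domain", n_excluded)
    return windows


class GeneIndex:
    """Per-chromosome sorted TSS arrays for fast window -> gene capture."""

    def __init__(self, genes: Sequence[GeneRecord]):
        self.genes = list(genes)
        self.ids = np.array([g.gene_id for g in self.genes], dtype=object)
        order: dict[str, list[int]] = {}
        for i, g in enumerate(self.genes):
            order.setdefault(g.chrom, []).append(i)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, idx in order.items():
            idx_arr = np.asarray(idx, dtype=np.int64)
            tss = np.array([self.genes[i].tss for i in idx], dtype=np.int64)
            sorter = np.argsort(tss, kind="stable")
            self._by_chrom[chrom] = (tss[sorter], idx_arr[sorter])

    def __len__(self) -> int:
        return len(self.genes)

    def capture_mask(self, windows: Iterable[GenomicInterval]) -> np.ndarray:
        """Boolean mask over genes: TSS inside >= 1 window (start-inclusive, end-exclusive)."""
        mask = np.zeros(len(self.genes), dtype=bool)
        for w in windows:
            entry = self._by_chrom.get(w.chrom)
            if entry is None:
                continue
            tss_sorted, gene_idx = entry
            lo = int(np.searchsorted(tss_sorted, w.start, side="left"))
            hi = int(np.searchsorted(tss_sorted, w.end, side="left"))
            if hi > lo:
                mask[gene_idx[lo:hi]] = True
        return mask


def capture_genes(
    windows: Sequence[GenomicInterval], genes: Sequence[GeneRecord] | GeneIndex
) -> set[str]:
    """Gene ids whose TSS satisfies window.start <= tss < window.end for >= 1 window.

    Each gene counts once no matter how many windows contain its TSS.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    mask = index.capture_mask(windows)
    return set(index.ids[mask])


def enrich_at_distance(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord] | GeneIndex,
    cluster: GeneCluster,
    d: int,
    chrom_sizes: ChromSizes,
    domains: DomainMap | None = None,
) -> EnrichmentResult:
    """Hypergeometric enrichment of ``cluster`` among genes within ±d bp of a peak.

    N = universe size, K = cluster size, n = captured universe genes,
    k = captured cluster genes; p = P(X >= k) for X ~ Hypergeom(N, K, n).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    unknown = cluster.members - set(index.ids)
    if unknown:
        raise ValueError(
            f"cluster {cluster.name!r} has {len(unknown)} ids outside the gene universe; "
            "resolve it with read_cluster first"
        )
    windows = extend_peaks(peaks, d, chrom_sizes, domains=domains)
    mask = index.capture_mask(windows)
    captured = set(index.ids[mask])
    k_ids = frozenset(captured & cluster.members)
    return EnrichmentResult.from_counts(
        distance_bp=d,
        N=len(index),
        K=len(cluster),
        n=len(captured),
        k=len(k_ids),
        captured_ids=k_ids,
        cluster=cluster.name,
    )


def proportion_within(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord] | GeneIndex,
    cluster: GeneCluster,
    d: int,
    chrom_sizes: ChromSizes,
) -> tuple[float, float]:
    """(k/K, n/N): proportion of the cluster and of all genes within ±d bp of a peak."""
    res = enrich_at_distance(peaks, genes, cluster, d, chrom_sizes)
    return res.prop_cluster, res.prop_universe


def distance_sweep(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord] | GeneIndex,
    clusters: Sequence[GeneCluster],
    distances: Sequence[int] = DEFAULT_DISTANCES,
    chrom_sizes: ChromSizes | None = None,
    domains: DomainMap | None = None,
) -> pd.DataFrame:
    """One enrichment row per (cluster, distance) over a strictly increasing grid.

    Within a cluster the captured counts n and k are non-decreasing in d
    (capture sets are nested).  A Bonferroni column across the grid is
    emitted additionally; the headline statistic stays the raw p-value, which
    is how distance-enrichment profiles are conventionally plotted.
    """
    if chrom_sizes is None:
        raise ValueError("distance_sweep requires a chrom_sizes table")
    distances = [int(d) for d in distances]
    if any(d < 0 for d in distances):
        raise ValueError("distances must be >= 0")
    if any(b <= a for a, b in zip(distances, distances[1:])):
        raise ValueError(f"distances must be strictly increasing, got {distances}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    rows = []
    for cluster in clusters:
        for d in distances:
            res = enrich_at_distance(peaks, index, cluster, d, chrom_sizes, domains=domains)
            rows.append(
                {
                    "cluster": cluster.name,
                    "distance_bp": d,
                    "N": res.N,
                    "K": res.K,
                    "n": res.n,
                    "k": res.k,
                    "p_upper": res.p_upper,
                    "neg_log10_p": res.neg_log10_p,
                    "fold": res.fold,
                    "prop_cluster": res.prop_cluster,
                    "prop_universe": res.prop_universe,
                }
            )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    table["p_bonferroni"] = np.minimum(1.0, table["p_upper"] * len(distances))
    return table
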