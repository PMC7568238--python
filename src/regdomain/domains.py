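"""TAD/subTAD domain maps and domain-level cistrome-transcriptome association.

A :class:`DomainMap` is a validated, non-overlapping set of chromatin domains
(TADs or subTADs — supplied as two separate maps, since "same TAD/subTAD" is
ill-posed when domains overlap).  The domain-level question: which genes share
a domain with at least one binding site, and is a DE cluster over-represented
among them?

The universe for the domain test is restricted to genes assigned to *some*
domain: a gene outside every TAD cannot share a TAD with a peak, and leaving
such genes in the background would inflate enrichment.  The "percentage of
all genes" comparison is computed on the same restricted universe; the
restriction is recorded in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome import GeneRecord, GenomicInterval
from .stats import EnrichmentResult

log = logging.getLogger(__name__)


class DomainMap:
    """Non-overlapping genomic domains with unique ids, indexed per chromosome."""

    def __init__(self, domains: Sequence[GenomicInterval]):
        labelled = []
        seen_ids: set[str] = set()
        for dom in sorted(domains, key=GenomicInterval.sort_key):
            dom_id = dom.name if dom.name else f"{dom.chrom}:{dom.start}-{dom.end}"
            if dom_id in seen_ids:
                raise ValueError(f"duplicate domain id {dom_id!r}")
            seen_ids.add(dom_id)
            labelled.append(
                GenomicInterval(dom.chrom, dom.start, dom.end, name=dom_id, strand=dom.strand)
            )
        self.domains: list[GenomicInterval] = labelled
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
        per_chrom: dict[str, list[GenomicInterval]] = {}
        for dom in labelled:
            per_chrom.setdefault(dom.chrom, []).append(dom)
        for chrom, doms in per_chrom.items():
            for prev, cur in zip(doms, doms[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"overlapping domains on {chrom}: "
                        f"{prev.name} [{prev.start}, {prev.end}) and {cur.name} [{cur.start}, {cur.end})"
                    )
            starts = np.array([d.start for d in doms], dtype=np.int64)
            ends = np.array([d.end for d in doms], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, doms)

    def __len__(self) -> int:
        return len(self.domains)

    def domain_at(self, chrom: str, pos: int) -> GenomicInterval | None:
        """The unique domain with start <= pos < end, or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, doms = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return doms[i]
        return None

    def overlapping(self, interval: GenomicInterval) -> list[GenomicInterval]:
        """Domains overlapping >= 1 bp with the interval (may be several: spanning peaks)."""
        entry = self._by_chrom.get(interval.chrom)
        if entry is None:
            return []
        starts, ends, doms = entry
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        return doms[lo:hi]


def assign_tss_to_domain(
    genes: Sequence[GeneRecord], domain_map: DomainMap
) -> dict[str, str | None]:
    """Map each gene id to the id of the domain containing its TSS, else None."""
    assignment: dict[str, str | None] = {}
    n_unassigned = 0
    for gene in genes:
        dom = domain_map.domain_at(gene.chrom, gene.tss)
        assignment[gene.gene_id] = dom.name if dom is not None else None
        if dom is None:
            n_unassigned += 1
    if n_unassigned:
        log.info("assign_tss_to_domain: %d of %d genes fall outside every domain",
                 n_unassigned, len(genes))
    return assignment


def flag_peak_domains(
    peaks: Sequence[GenomicInterval], domain_map: DomainMap
) -> set[str]:
    """Ids of domains overlapping >= 1 bp with >= 1 peak (spanning peaks flag both sides)."""
    flagged: set[str] = set()
    for peak in peaks:
        for dom in domain_map.overlapping(peak):
            flagged.add(dom.name)
    return flagged


@dataclass
class DomainEnrichment:
    """Domain-level enrichment: counts, p-value and the headline percentages."""

    result: EnrichmentResult
    pct_cluster: float  #: 100 * (cluster genes sharing a domain with a peak) / (cluster genes in any domain)
    pct_all: float  #: same percentage over the whole domain-assigned universe
    n_genes_outside_domains: int
    n_domains_flagged: int


def domain_enrichment(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneRecord],
    cluster,
    domain_map: DomainMap,
    assignment: Mapping[str, str | None] | None = None,
) -> DomainEnrichment:
    """Enrichment of a gene cluster among genes sharing a TAD/subTAD with a peak.

    Universe N' = genes assigned to any domain; n = those in peak-flagged
    domains; K', k analogous for the cluster; hypergeometric upper tail on
    (N', K', n, k).  Raises if no cluster gene lies in any domain.
    """
    if assignment is None:
        assignment = assign_tss_to_domain(genes, domain_map)
    flagged = flag_peak_domains(peaks, domain_map)

    assigned = {gid: dom for gid, dom in assignment.items() if dom is not None}
    n_outside = len(assignment) - len(assigned)
    members = cluster.members
    K_prime = sum(1 for gid in members if gid in assigned)
    if K_prime == 0:
        raise ValueError(
            f"cluster {cluster.name!r}: no member gene lies inside any domain; "
            "domain enrichment is undefined"
        )
    n = sum(1 for dom in assigned.values() if dom in flagged)
    k_ids = frozenset(
        gid for gid in members if assigned.get(gid) in flagged and gid in assigned
    )
    result = EnrichmentResult.from_counts(
        distance_bp="domain",
        N=len(assigned),
        K=K_prime,
        n=n,
        k=len(k_ids),
        captured_ids=k_ids,
        cluster=cluster.name,
    )
    return DomainEnrichment(
        result=result,
        pct_cluster=100.0 * len(k_ids) / K_prime,
        pct_all=100.0 * n / len(assigned) if assigned else 0.0,
        n_genes_outside_domains=n_outside,
        n_domains_flagged=len(flagged),
    )
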