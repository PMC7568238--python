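"""PWM scanning and motif fold-enrichment against matched background regions.

A region "contains" a motif when its best log-odds window score, over both
strands and all offsets, reaches the PWM threshold (presence/absence — hit
counts per region are not used).  Fold enrichment is the percentage of target
regions containing the motif divided by the percentage of background regions
containing it; significance is a hypergeometric upper tail on the
presence/absence table over the pooled regions.  The background set stands in
for matched control regions such as open-chromatin sites.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import ChromSizes, GenomicInterval
from .stats import hypergeom_log10_upper_tail, hypergeom_upper_tail

log = logging.getLogger(__name__)

BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G

# byte -> base index; anything unknown scores like N (index 4)
_ENCODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_FRACTION = 0.8


@dataclass
class PWM:
    """Position weight matrix with background frequencies and a hit threshold.

    ``probs`` is an L x 4 matrix (columns A, C, G, T) of per-position base
    probabilities, already pseudocounted so every entry is positive; scores
    are log2(p / background) summed over positions.  ``threshold`` is the
    minimum best-window log-odds score for a region to count as containing
    the motif; by default 80% of the maximum attainable score.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"probs must be L x 4, got shape {self.probs.shape}")
        if np.any(self.probs <= 0) or np.any(self.background <= 0):
            raise ValueError("probabilities must be strictly positive (apply a pseudocount)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1 within 1e-6")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1 within 1e-6")
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLD_FRACTION * self.max_score

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 score matrix: log2(p/bg) per base, column 4 = per-position minimum (N)."""
        lo = np.log2(self.probs / self.background[None, :])
        return np.column_stack([lo, lo.min(axis=1)])

    @property
    def max_score(self) -> float:
        return float(np.log2(self.probs / self.background[None, :]).max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        threshold: float | None = None,
    ) -> "PWM":
        """Build from an L x 4 (or JASPAR-style 4 x L) count matrix.

        Counts are normalised to probabilities per position, then the
        pseudocount is added and the row re-normalised, so zero counts become
        small positive probabilities.
        """
        counts = np.asarray(counts, dtype=np.float64)
        if counts.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        if counts.shape[0] == 4 and counts.shape[1] != 4:
            counts = counts.T
        if counts.shape[1] != 4:
            raise ValueError(f"count matrix must have 4 base columns, got {counts.shape}")
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("every position needs a positive total count")
        probs = counts / totals
        probs = (probs + pseudocount) / (1.0 + 4 * pseudocount)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=np.float64)
        return cls(name=name, probs=probs, background=bg, threshold=threshold)

    @classmethod
    def from_jaspar(
        cls,
        path: str | Path,
        background: Sequence[float] | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        threshold: float | None = None,
    ) -> "PWM":
        """Read a JASPAR-format count matrix (4 labelled base rows)."""
        with open(path) as fh:
            motif = bio_motifs.read(fh, "jaspar")
        counts = np.array([list(motif.counts[b]) for b in BASES], dtype=np.float64)
        name = motif.name or motif.matrix_id or Path(path).stem
        return cls.from_counts(name, counts, background=background,
                              pseudocount=pseudocount, threshold=threshold)


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int array (A,C,G,T = 0..3; N and anything else = 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_scores(seq: str, pwm: PWM) -> np.ndarray:
    """Per-offset best-of-both-strands log-odds scores for every motif-length window."""
    L = len(pwm)
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} shorter than motif length {L}")
    enc = encode_sequence(seq)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    scores = pwm.log_odds
    fwd = scores[np.arange(L)[None, :], windows].sum(axis=1)
    # reverse strand: score the reverse complement of the PWM on the forward text
    rc = scores[::-1].copy()
    rc[:, :4] = rc[:, :4][:, ::-1]  # complement base columns (A<->T, C<->G)
    rev = rc[np.arange(L)[None, :], windows].sum(axis=1)
    return np.maximum(fwd, rev)


def best_hit_score(seq: str, pwm: PWM) -> float:
    """Maximum log-odds score over both strands and all offsets."""
    return float(window_scores(seq, pwm).max())


def region_contains_motif(seq: str, pwm: PWM) -> bool:
    return best_hit_score(seq, pwm) >= pwm.threshold


def windows_around_centers(
    peaks: Sequence[GenomicInterval],
    width: int,
    chrom_sizes: ChromSizes | None = None,
) -> list[GenomicInterval]:
    """Fixed-width scan windows centred on peak midpoints, clipped at chromosome bounds.

    For a peak [s, e): centre c = floor((s+e)/2), window [c - width/2, c + width/2).
    """
    if width <= 0 or width % 2:
        raise ValueError(f"window width must be positive and even, got {width}")
    half = width // 2
    out = []
    for peak in peaks:
        c = peak.midpoint
        start = max(0, c - half)
        end = c + half
        if chrom_sizes is not None:
            end = min(end, chrom_sizes.require(peak.chrom))
        out.append(GenomicInterval(peak.chrom, start, end, name=peak.name))
    return out


@dataclass
class RegionSeqSet:
    """Regions paired with their uppercase DNA sequences (alphabet ACGTN)."""

    regions: list[GenomicInterval]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.sequences):
            raise ValueError("regions and sequences must align one-to-one")
        self.sequences = [s.upper() for s in self.sequences]
        for region, seq in zip(self.regions, self.sequences):
            if len(seq) != len(region):
                raise ValueError(
                    f"sequence length {len(seq)} != span of {region.chrom}:{region.start}-{region.end}"
                )
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"sequence for {region.chrom} contains non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return len(self.regions)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RegionSeqSet":
        """Load regions from FASTA; headers like ``chrom:start-end`` restore coordinates."""
        regions, seqs = [], []
        coord = re.compile(r"^(\S+):(\d+)-(\d+)$")
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            m = coord.match(rec.id)
            if m:
                regions.append(GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3))))
            else:
                regions.append(GenomicInterval(rec.id, 0, len(seq)))
            seqs.append(seq)
        if not regions:
            raise ValueError(f"no sequences found in {path}")
        return cls(regions, seqs)

    @classmethod
    def from_bed_and_genome(
        cls, regions: Sequence[GenomicInterval], genome_fasta: str | Path
    ) -> "RegionSeqSet":
        """Extract region sequences from an indexed genome FASTA."""
        from pyfaidx import Fasta

        genome = Fasta(str(genome_fasta))
        seqs = [str(genome[r.chrom][r.start : r.end]).upper() for r in regions]
        return cls(list(regions), seqs)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=f"{r.chrom}:{r.start}-{r.end}", description="")
            for r, seq in zip(self.regions, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")

    def hit_mask(self, pwm: PWM) -> np.ndarray:
        return np.array([region_contains_motif(s, pwm) for s in self.sequences], dtype=bool)


@dataclass
class MotifEnrichment:
    """Motif presence percentages, fold enrichment, and hypergeometric p."""

    pwm_name: str
    n_target: int
    n_background: int
    k_target: int  #: target regions containing the motif
    k_background: int
    pct_target: float
    pct_background: float
    fold: float
    p_upper: float
    neg_log10_p: float


def fold_enrichment(target: RegionSeqSet, background: RegionSeqSet, pwm: PWM) -> MotifEnrichment:
    """Fold enrichment of a motif in target vs background regions.

    FE = pct_target / pct_background on presence/absence calls.  Significance
    is the hypergeometric upper tail over the pooled universe: N = |T| + |B|,
    K = |T|, n = total containing regions, k = target containing regions.
    FE is NaN when the background percentage is zero but targets have hits;
    when neither set has a hit, FE = 1 is implied and the degenerate case is
    logged.
    """
    if len(target) == 0 or len(background) == 0:
        raise ValueError("target and background region sets must both be non-empty")
    t_hits = int(target.hit_mask(pwm).sum())
    b_hits = int(background.hit_mask(pwm).sum())
    pct_t = 100.0 * t_hits / len(target)
    pct_b = 100.0 * b_hits / len(background)
    if pct_b > 0:
        fold = pct_t / pct_b
    elif t_hits > 0:
        fold = float("nan")
    else:
        log.warning("fold_enrichment(%s): no hits in either set; FE undefined, reporting 1", pwm.name)
        fold = 1.0
    N = len(target) + len(background)
    K = len(target)
    n = t_hits + b_hits
    k = t_hits
    p = hypergeom_upper_tail(N, K, n, k)
    return MotifEnrichment(
        pwm_name=pwm.name,
        n_target=len(target),
        n_background=len(background),
        k_target=t_hits,
        k_background=b_hits,
        pct_target=pct_t,
        pct_background=pct_b,
        fold=fold,
        p_upper=p,
        neg_log10_p=-hypergeom_log10_upper_tail(N, K, n, k),
    )
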