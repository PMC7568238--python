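"""Linked synthetic studies with planted cistrome-transcriptome structure.

The generator emits everything the analysis pipeline consumes — gene
annotation, peak set, DE gene clusters, domain map, and motif-planted region
sequences — with known ground truth, so every stage of the analysis is
testable without sequencing data.

Planting model
--------------
Capture structure is decided gene-by-gene, then realised geometrically:

* Every gene draws a *tier*: captured within the calibration distance
  (default 5 kbp) of some peak, captured only within a longer plant distance,
  or not planted.  Cluster genes draw from their cluster's capture
  probabilities; all other genes draw from a background rate derated so that
  the expected genome-wide proportion of genes within the calibration
  distance equals ``background_capture_prob`` (the "15% of all genes" scale).
* Each planted gene receives one dedicated peak whose extended window at its
  tier distance contains the TSS, and **every** peak is placed so that its
  ±calibration-distance window contains no TSS of a gene outside the
  calibration tier.  Capture at the calibration distance therefore equals the
  Bernoulli tier draw exactly, which is what makes planted proportions
  recoverable to binomial precision.
* Leftover peaks ("desert" peaks) are scattered at hotspots near planted
  peaks, mimicking the clustering of real binding sites; they respect the
  same avoidance rule, so they change nothing at the calibration distance
  while keeping longer-range capture from saturating.

A single NumPy Generator seeded from the config drives every draw, in a fixed
order, so two runs with the same (config, seed) are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import (
    ChromSizes,
    GeneCluster,
    GeneRecord,
    GenomicInterval,
    write_bed,
    write_chrom_sizes,
    write_cluster,
    write_genes,
)
from .motifs import PWM, RegionSeqSet, windows_around_centers

log = logging.getLogger(__name__)

#: Synthetic RORE-like count matrix (rows A, C, G, T): an AGGTCA-hexamer core
#: with an A/T-rich 5' flank.  A stand-in PWM for testing, not a database motif.
RORE_LIKE_COUNTS = np.array(
    [
        # W   A   N   T   R   G   G   T   C   A
        [55, 70, 25, 3, 40, 3, 3, 3, 3, 91],  # A
        [3, 12, 25, 3, 3, 3, 3, 3, 91, 3],    # C
        [3, 12, 25, 3, 54, 91, 91, 3, 3, 3],  # G
        [39, 6, 25, 91, 3, 3, 3, 91, 3, 3],   # T
    ],
    dtype=float,
)


def default_pwm() -> PWM:
    return PWM.from_counts("RORE_like_synthetic", RORE_LIKE_COUNTS)


@dataclass
class ClusterSpec:
    """One DE gene cluster: size, planted capture probability and plant distance.

    ``capture_prob`` is the probability that a cluster gene lies within
    ``plant_distance_bp`` of a peak; ``None`` means the cluster is unplanted
    and its genes behave exactly like background (the null-control cluster).
    ``far_capture_prob``/``far_distance_bp`` optionally add a second, longer
    tier (e.g. 87% within 50 kbp on top of 55% within 5 kbp).
    """

    name: str
    size: int
    capture_prob: float | None
    plant_distance_bp: int
    far_capture_prob: float | None = None
    far_distance_bp: int | None = None


@dataclass
class MotifSpec:
    """Planting rates for the motif-region simulation."""

    plant_rate_target: float = 0.6
    plant_rate_background: float = 0.1
    region_width: int = 200
    n_background_regions: int | None = None  # None -> match the target count


def _default_clusters() -> list[ClusterSpec]:
    # Liver-scale model: 140 planted up-genes + 82 unplanted down-genes
    # (222 DE genes total); plus a 3,000-gene (15%-of-genome) cluster with
    # weaker, longer-range planting, the global-knockout regime.
    return [
        ClusterSpec("liver_up", 140, 0.55, 5_000, far_capture_prob=0.87, far_distance_bp=50_000),
        ClusterSpec("liver_down", 82, None, 5_000),
        ClusterSpec("global_ko_up", 3_000, 0.55, 50_000),
    ]


@dataclass
class SimConfig:
    """Study-scale parameters; the defaults are the conditions the analyses assume."""

    seed: int = 0
    n_chroms: int = 5
    chrom_length_bp: int = 180_000_000
    n_genes: int = 20_000
    n_peaks: int = 8_660
    cluster_specs: list[ClusterSpec] = field(default_factory=_default_clusters)
    background_capture_prob: float = 0.15
    calibration_distance_bp: int = 5_000
    peak_width_min: int = 200
    peak_width_max: int = 800
    n_domains_per_chrom: int = 800  # ~225 kb domains on a 180 Mb chromosome (subTAD scale)
    domain_gap_fraction: float = 0.0
    hotspot_spread_bp: int = 25_000
    motif: MotifSpec = field(default_factory=MotifSpec)

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length_bp < 1:
            raise ValueError("need >= 1 chromosome of positive length")
        if not (0 <= self.background_capture_prob <= 1):
            raise ValueError("background_capture_prob must be in [0, 1]")
        if not (0 < self.peak_width_min <= self.peak_width_max):
            raise ValueError("peak width range must satisfy 0 < min <= max")
        for spec in self.cluster_specs:
            if spec.size <= 0:
                raise ValueError(f"cluster {spec.name!r}: size must be positive")
            if spec.capture_prob is not None and not (0 <= spec.capture_prob <= 1):
                raise ValueError(f"cluster {spec.name!r}: capture_prob must be in [0, 1]")
            if spec.plant_distance_bp >= self.chrom_length_bp:
                raise ValueError(f"cluster {spec.name!r}: plant_distance exceeds chromosome length")
            if (spec.far_capture_prob is None) != (spec.far_distance_bp is None):
                raise ValueError(f"cluster {spec.name!r}: far tier needs both prob and distance")
            if spec.far_distance_bp is not None and spec.far_distance_bp <= spec.plant_distance_bp:
                raise ValueError(f"cluster {spec.name!r}: far distance must exceed plant distance")
        if sum(s.size for s in self.cluster_specs) > self.n_genes:
            raise ValueError("cluster sizes exceed the number of genes")
        for rate in (self.motif.plant_rate_target, self.motif.plant_rate_background):
            if not (0 <= rate <= 1):
                raise ValueError("motif plant rates must be in [0, 1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cluster_specs" in raw:
            raw["cluster_specs"] = [ClusterSpec(**c) for c in raw["cluster_specs"]]
        if "motif" in raw:
            raw["motif"] = MotifSpec(**raw["motif"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ChromSizes, list[GeneRecord]]:
    """Uniformly placed TSSs with random strands across the configured chromosomes."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    margin = 10_000
    usable = config.n_chroms * max(0, config.chrom_length_bp - 2 * margin)
    if config.n_genes > usable:
        raise ValueError(
            f"cannot place {config.n_genes} distinct TSSs in {usable} usable bp"
        )
    sizes = ChromSizes({name: config.chrom_length_bp for name in config.chrom_names})
    chrom_idx = rng.integers(0, config.n_chroms, size=config.n_genes)
    genes: list[GeneRecord] = []
    gene_no = 0
    for ci, chrom in enumerate(config.chrom_names):
        count = int((chrom_idx == ci).sum())
        positions = np.array([], dtype=np.int64)
        while len(positions) < count:
            draw = rng.integers(margin, config.chrom_length_bp - margin, size=count - len(positions))
            positions = np.unique(np.concatenate([positions, draw]))
        positions = np.sort(positions[:count])
        strands = rng.integers(0, 2, size=count)
        lengths = rng.integers(1_000, 50_001, size=count)
        for pos, s_bit, length in zip(positions, strands, lengths):
            gene_no += 1
            gene_id = f"gene{gene_no:05d}"
            pos, length = int(pos), int(length)
            if s_bit == 0:
                interval = GenomicInterval(
                    chrom, pos, min(pos + length, config.chrom_length_bp),
                    name=gene_id, strand="+",
                )
            else:
                interval = GenomicInterval(
                    chrom, max(0, pos + 1 - length), pos + 1, name=gene_id, strand="-"
                )
            genes.append(GeneRecord(gene_id, interval))
    return sizes, genes


def simulate_clusters(
    config: SimConfig, genes: Sequence[GeneRecord], rng: np.random.Generator
) -> dict[str, GeneCluster]:
    """Disjoint random gene subsets, one per cluster spec."""
    perm = rng.permutation(len(genes))
    clusters: dict[str, GeneCluster] = {}
    offset = 0
    for spec in config.cluster_specs:
        idx = perm[offset : offset + spec.size]
        offset += spec.size
        clusters[spec.name] = GeneCluster(
            spec.name, frozenset(genes[i].gene_id for i in idx)
        )
    return clusters


# ---------------------------------------------------------------------------
# planted peaks


def _derated_background_rate(config: SimConfig) -> float:
    """Per-gene background rate so the genome-wide expected proportion hits the target.

    Clusters planted at the calibration distance contribute their own capture
    probability to the genome-wide proportion; the remaining genes absorb the
    difference.
    """
    N = config.n_genes
    calib = config.calibration_distance_bp
    planted_mass = 0.0
    planted_genes = 0
    for spec in config.cluster_specs:
        if spec.capture_prob is not None and spec.plant_distance_bp == calib:
            planted_mass += spec.size * spec.capture_prob
            planted_genes += spec.size
    q = (config.background_capture_prob * N - planted_mass) / (N - planted_genes)
    if not (0 <= q <= 1):
        raise ValueError(
            f"infeasible background rate: clusters planted at {calib} bp imply a "
            f"per-gene background rate of {q:.4f} to reach a genome-wide proportion "
            f"of {config.background_capture_prob}"
        )
    return q


def _free_segments(
    lo: int, hi: int, w: int, d: int, protected: np.ndarray
) -> list[tuple[int, int]]:
    """Inclusive candidate segments [lo, hi] for a peak start s of width w, after
    removing every s for which the window [s-d, s+w+d) contains a protected TSS."""
    if hi < lo:
        return []
    # protected u forbids s in [u-w-d+1, u+d]
    i0 = int(np.searchsorted(protected, lo - d, side="left"))
    i1 = int(np.searchsorted(protected, hi + w + d, side="left"))
    segments: list[tuple[int, int]] = []
    cur = lo
    for u in protected[i0:i1]:
        a, b = int(u) - w - d + 1, int(u) + d
        if a > cur:
            segments.append((cur, min(a - 1, hi)))
        cur = max(cur, b + 1)
        if cur > hi:
            break
    if cur <= hi:
        segments.append((cur, hi))
    return segments


def _sample_from_segments(segments: list[tuple[int, int]], rng: np.random.Generator) -> int:
    total = sum(b - a + 1 for a, b in segments)
    r = int(rng.integers(0, total))
    for a, b in segments:
        span = b - a + 1
        if r < span:
            return a + r
        r -= span
    raise AssertionError("unreachable")


def _draw_tiers(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    clusters: dict[str, GeneCluster],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (group index, tier distance) draws; tier 0 means unplanted."""
    n = len(genes)
    calib = config.calibration_distance_bp
    q = _derated_background_rate(config)
    gene_pos = {g.gene_id: i for i, g in enumerate(genes)}
    group = np.zeros(n, dtype=np.int64)  # 0 = background
    for gi, spec in enumerate(config.cluster_specs, start=1):
        for gid in clusters[spec.name].members:
            group[gene_pos[gid]] = gi
    tiers = np.zeros(n, dtype=np.int64)
    # background + unplanted clusters first, then each cluster, in spec order
    bg_like = group == 0
    for gi, spec in enumerate(config.cluster_specs, start=1):
        if spec.capture_prob is None:
            bg_like |= group == gi
    idx = np.flatnonzero(bg_like)
    tiers[idx[rng.random(len(idx)) < q]] = calib
    for gi, spec in enumerate(config.cluster_specs, start=1):
        if spec.capture_prob is None:
            continue
        idx = np.flatnonzero(group == gi)
        if spec.plant_distance_bp == calib:
            hit = rng.random(len(idx)) < spec.capture_prob
            tiers[idx[hit]] = calib
            if spec.far_capture_prob is not None:
                p2 = (spec.far_capture_prob - spec.capture_prob) / (1 - spec.capture_prob)
                if not (0 <= p2 <= 1):
                    raise ValueError(f"cluster {spec.name!r}: far tier probability infeasible")
                rest = idx[~hit]
                tiers[rest[rng.random(len(rest)) < p2]] = spec.far_distance_bp
        else:
            # background marking at the calibration distance, then the
            # cluster's own longer tier on top
            hit1 = rng.random(len(idx)) < q
            tiers[idx[hit1]] = calib
            p2 = (spec.capture_prob - q) / (1 - q)
            if not (0 <= p2 <= 1):
                raise ValueError(
                    f"cluster {spec.name!r}: capture_prob {spec.capture_prob} below the "
                    f"background rate {q:.4f}; longer-tier planting infeasible"
                )
            rest = idx[~hit1]
            tiers[rest[rng.random(len(rest)) < p2]] = spec.plant_distance_bp
    return group, tiers


def _resolve_blocked(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    group: np.ndarray,
    tiers: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Swap calibration-tier status away from genes whose peak cannot be placed.

    A calibration-tier gene is *blocked* when every admissible peak start
    would put a protected (non-calibration-tier) TSS inside the peak's
    calibration window — typically a gene squeezed between two close,
    unplanted neighbours.  Blocked genes trade status with a random unplanted
    gene of the same group, preserving the planted count; the rare residual
    failures are demoted and returned.
    """
    calib = config.calibration_distance_bp
    w_max = config.peak_width_max
    L = config.chrom_length_bp
    chrom_of = np.array([g.chrom for g in genes])
    tss = np.array([g.tss for g in genes], dtype=np.int64)

    def blocked_indices() -> np.ndarray:
        protected: dict[str, np.ndarray] = {}
        for chrom in config.chrom_names:
            sel = (chrom_of == chrom) & (tiers != calib)
            protected[chrom] = np.sort(tss[sel])
        out = []
        for i in np.flatnonzero(tiers == calib):
            t = int(tss[i])
            lo = max(0, t - w_max - calib + 1)
            hi = min(L - w_max, t + calib)
            if not _free_segments(lo, hi, w_max, calib, protected[chrom_of[i]]):
                out.append(i)
        return np.asarray(out, dtype=np.int64)

    demoted = 0
    for _ in range(50):
        blocked = blocked_indices()
        if len(blocked) == 0:
            return demoted
        for i in blocked:
            pool = np.flatnonzero((group == group[i]) & (tiers == 0))
            tiers[i] = 0
            if len(pool):
                tiers[int(pool[int(rng.integers(0, len(pool)))])] = calib
            else:
                demoted += 1
    leftovers = len(blocked_indices())
    if leftovers:
        tiers[blocked_indices()] = 0
        demoted += leftovers
        log.warning("planting: demoted %d genes whose peaks could not be placed", demoted)
    return demoted


def simulate_peaks_planted(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    clusters: dict[str, GeneCluster] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicInterval], pd.DataFrame]:
    """Peaks with planted proximity structure plus a per-peak truth table.

    Returns (sorted peak list, truth table).  The truth table has one row per
    peak: coordinates, kind (``planted``/``desert``), the gene it was planted
    for (or ``none``) and the tier distance.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if clusters is None:
        clusters = simulate_clusters(config, genes, rng)
    calib = config.calibration_distance_bp
    L = config.chrom_length_bp
    group, tiers = _draw_tiers(config, genes, clusters, rng)
    _resolve_blocked(config, genes, group, tiers, rng)

    chrom_of = np.array([g.chrom for g in genes])
    tss = np.array([g.tss for g in genes], dtype=np.int64)
    protected: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        sel = (chrom_of == chrom) & (tiers != calib)
        protected[chrom] = np.sort(tss[sel])

    raw: list[tuple[str, int, int, str, str, int]] = []  # chrom, start, end, kind, target, tier
    planted_order = np.flatnonzero(tiers > 0)
    n_demoted = 0
    for i in planted_order:
        g = genes[int(i)]
        t = int(tss[i])
        tier = int(tiers[i])
        w = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
        lo = max(0, t - w - tier + 1)
        hi = min(L - w, t + tier)
        segments = _free_segments(lo, hi, w, calib, protected[g.chrom])
        if tier > calib:
            # longer-tier peaks must not capture their own gene at the
            # calibration distance; the gene is protected, so its own
            # forbidden zone already carves out the near range.
            pass
        if not segments:
            n_demoted += 1
            tiers[i] = 0
            continue
        s = _sample_from_segments(segments, rng)
        raw.append((g.chrom, s, s + w, "planted", g.gene_id, tier))
    if n_demoted:
        log.warning("planting: %d planted genes demoted at placement time", n_demoted)

    n_planted = len(raw)
    n_desert = config.n_peaks - n_planted
    if n_desert < 0:
        raise ValueError(
            f"infeasible peak budget: capture probabilities require {n_planted} planted "
            f"peaks but n_peaks={config.n_peaks}; raise n_peaks or lower capture rates"
        )
    anchors = [(c, s) for c, s, *_ in raw]
    placed = 0
    while placed < n_desert:
        batch = max(64, 2 * (n_desert - placed))
        if anchors:
            a_idx = rng.integers(0, len(anchors), size=batch)
            offs = rng.integers(-config.hotspot_spread_bp, config.hotspot_spread_bp + 1, size=batch)
            cand_chrom = [anchors[j][0] for j in a_idx]
            cand_s = np.array([anchors[j][1] for j in a_idx], dtype=np.int64) + offs
        else:
            ci = rng.integers(0, config.n_chroms, size=batch)
            cand_chrom = [config.chrom_names[j] for j in ci]
            cand_s = rng.integers(0, L, size=batch)
        widths = rng.integers(config.peak_width_min, config.peak_width_max + 1, size=batch)
        for chrom, s, w in zip(cand_chrom, cand_s, widths):
            s, w = int(s), int(w)
            if s < 0 or s + w > L:
                continue
            prot = protected[chrom]
            i0 = int(np.searchsorted(prot, s - calib, side="left"))
            i1 = int(np.searchsorted(prot, s + w + calib, side="left"))
            if i1 > i0:  # would capture a protected TSS at the calibration distance
                continue
            raw.append((chrom, s, s + w, "desert", "none", 0))
            placed += 1
            if placed == n_desert:
                break

    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    peaks = []
    rows = []
    for j, (chrom, s, e, kind, target, tier) in enumerate(raw, start=1):
        name = f"peak{j:05d}"
        peaks.append(GenomicInterval(chrom, s, e, name=name))
        rows.append(
            {
                "peak": name,
                "chrom": chrom,
                "start": s,
                "end": e,
                "kind": kind,
                "target_gene": target,
                "tier_distance_bp": tier,
            }
        )
    return peaks, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# domains


def simulate_domains(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[GenomicInterval]:
    """A contiguous non-overlapping domain partition with random breakpoints.

    With ``domain_gap_fraction`` = 0 the domains tile each chromosome exactly;
    otherwise each domain cedes its trailing fraction to an inter-domain gap.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.chrom_length_bp
    gap = config.domain_gap_fraction
    if not (0 <= gap < 1):
        raise ValueError("domain_gap_fraction must be in [0, 1)")
    domains = []
    for chrom in config.chrom_names:
        n_cuts = config.n_domains_per_chrom - 1
        cuts = np.array([], dtype=np.int64)
        while len(cuts) < n_cuts:
            draw = rng.integers(1, L, size=n_cuts - len(cuts))
            cuts = np.unique(np.concatenate([cuts, draw]))
        bounds = np.concatenate([[0], np.sort(cuts[:n_cuts]), [L]])
        for di, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
            a, b = int(a), int(b)
            keep = b - a if gap == 0 else max(1, round((1 - gap) * (b - a)))
            domains.append(GenomicInterval(chrom, a, a + keep, name=f"{chrom}_d{di:04d}"))
    return domains


# ---------------------------------------------------------------------------
# sequences


def simulate_sequences(
    regions: Sequence[GenomicInterval],
    pwm: PWM,
    plant_rate: float,
    rng: np.random.Generator,
) -> tuple[RegionSeqSet, pd.DataFrame]:
    """Background-composition sequences with motif instances planted at a rate.

    Each region gets i.i.d. bases from the PWM's background frequencies; with
    probability ``plant_rate`` one instance sampled column-wise from the PWM
    is written at a uniform offset on a uniform strand.  The plant log
    records every instance (region, offset, strand).
    """
    L_motif = len(pwm)
    for r in regions:
        if len(r) < L_motif:
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} is shorter than the motif ({L_motif} bp)"
            )
    bases = np.array(list("ACGT"))
    cum = np.cumsum(pwm.background)
    lengths = [len(r) for r in regions]
    flat = np.searchsorted(cum, rng.random(sum(lengths)), side="right")
    np.clip(flat, 0, 3, out=flat)
    seqs: list[np.ndarray] = []
    pos = 0
    for n in lengths:
        seqs.append(flat[pos : pos + n].copy())
        pos += n
    plant = rng.random(len(regions)) < plant_rate
    offsets = np.array([rng.integers(0, n - L_motif + 1) for n in lengths], dtype=np.int64)
    strands = rng.integers(0, 2, size=len(regions))
    pcum = np.cumsum(pwm.probs, axis=1)
    rows = []
    for i, region in enumerate(regions):
        if not plant[i]:
            rows.append({"region": f"{region.chrom}:{region.start}-{region.end}",
                         "planted": False, "offset": -1, "strand": "."})
            continue
        inst = np.array(
            [int(np.searchsorted(pcum[j], rng.random(), side="right")) for j in range(L_motif)],
            dtype=np.int64,
        )
        np.clip(inst, 0, 3, out=inst)
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            inst = (3 - inst)[::-1]  # reverse complement under A,C,G,T = 0..3
        off = int(offsets[i])
        seqs[i][off : off + L_motif] = inst
        rows.append({"region": f"{region.chrom}:{region.start}-{region.end}",
                     "planted": True, "offset": off, "strand": strand})
    seq_strings = ["".join(bases[s]) for s in seqs]
    return RegionSeqSet(list(regions), seq_strings), pd.DataFrame(rows)


def simulate_motif_regions(
    config: SimConfig,
    n_target: int,
    n_background: int,
    rng: np.random.Generator,
    pwm: PWM | None = None,
) -> tuple[RegionSeqSet, RegionSeqSet, pd.DataFrame, pd.DataFrame]:
    """Standalone target/background region sets planted at the configured rates."""
    pwm = default_pwm() if pwm is None else pwm
    width = config.motif.region_width
    targets = [GenomicInterval("target_regions", i * width, (i + 1) * width) for i in range(n_target)]
    bgs = [GenomicInterval("background_regions", i * width, (i + 1) * width) for i in range(n_background)]
    t_set, t_log = simulate_sequences(targets, pwm, config.motif.plant_rate_target, rng)
    b_set, b_log = simulate_sequences(bgs, pwm, config.motif.plant_rate_background, rng)
    return t_set, b_set, t_log, b_log


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyPaths:
    root: Path
    chrom_sizes: Path
    genes: Path
    peaks: Path
    clusters: dict[str, Path]
    domains: Path
    target_regions: Path
    background_regions: Path
    pwm_jaspar: Path
    truth_dir: Path


def _write_jaspar(pwm_counts: np.ndarray, name: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} {name}\n")
        for base, row in zip("ACGT", pwm_counts):
            values = " ".join(str(int(v)) for v in row)
            fh.write(f"{base} [ {values} ]\n")


def simulate_study(config: SimConfig, outdir: str | Path) -> StudyPaths:
    """Emit a complete, internally consistent study fixture into ``outdir``.

    One seeded stream drives annotation -> clusters -> peaks -> domains ->
    sequences in that fixed order; identical (config, seed) gives
    byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "clusters").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)

    sizes, genes = simulate_annotation(config, rng)
    clusters = simulate_clusters(config, genes, rng)
    peaks, truth = simulate_peaks_planted(config, genes, clusters, rng)
    domains = simulate_domains(config, rng)
    pwm = default_pwm()
    target_regions = windows_around_centers(peaks, config.motif.region_width, sizes)
    n_bg = config.motif.n_background_regions or len(target_regions)
    bg_regions = []
    widths = config.motif.region_width
    ci = rng.integers(0, config.n_chroms, size=n_bg)
    starts = rng.integers(0, config.chrom_length_bp - widths, size=n_bg)
    for c, s in zip(ci, starts):
        bg_regions.append(GenomicInterval(config.chrom_names[int(c)], int(s), int(s) + widths))
    t_set, t_log = simulate_sequences(target_regions, pwm, config.motif.plant_rate_target, rng)
    b_set, b_log = simulate_sequences(bg_regions, pwm, config.motif.plant_rate_background, rng)

    paths = StudyPaths(
        root=outdir,
        chrom_sizes=outdir / "chrom.sizes",
        genes=outdir / "genes.bed",
        peaks=outdir / "peaks.bed",
        clusters={name: outdir / "clusters" / f"{name}.txt" for name in clusters},
        domains=outdir / "tads.bed",
        target_regions=outdir / "target_regions.fa",
        background_regions=outdir / "background_regions.fa",
        pwm_jaspar=outdir / "motif.jaspar",
        truth_dir=outdir / "truth",
    )
    write_chrom_sizes(sizes, paths.chrom_sizes)
    write_genes(genes, paths.genes)
    write_bed(peaks, paths.peaks)
    for name, cluster in clusters.items():
        write_cluster(cluster, paths.clusters[name])
    write_bed(domains, paths.domains)
    t_set.to_fasta(paths.target_regions)
    b_set.to_fasta(paths.background_regions)
    _write_jaspar(RORE_LIKE_COUNTS, pwm.name, paths.pwm_jaspar)
    truth.to_csv(paths.truth_dir / "peaks.tsv", sep="\t", index=False)
    t_log.to_csv(paths.truth_dir / "target_region_plants.tsv", sep="\t", index=False)
    b_log.to_csv(paths.truth_dir / "background_region_plants.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")
    return paths
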