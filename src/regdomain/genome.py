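"""Coordinate model and readers/writers for the flat-file formats the pipeline touches.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start`` .. ``end - 1``, and every containment
test in the package is start-inclusive / end-exclusive.  Chromosome names are
taken verbatim; nothing normalises ``chr1`` against ``1`` — mismatched
namespaces between files are surfaced as hard errors by the validators rather
than silently producing empty overlaps.

The TSS of a gene is its strand-resolved 5' end: ``start`` on the ``+``
strand, ``end - 1`` (the last covered base) on the ``-`` strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

_VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed input file (bad coordinates, duplicate ids, bad strand...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span: the unit of peaks, windows and domains."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>= 1 bp overlap under half-open semantics (abutting intervals do not overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneRecord:
    """A gene with a strand-resolved TSS; the gene's point location in all analyses."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r} needs an explicit strand, got {self.interval.strand!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """TSS position: start on +, end - 1 on - (last covered base, half-open)."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp; lengths strictly positive."""

    def __init__(self, mapping: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(mapping)
        for chrom, length in self.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    def require(self, chrom: str) -> int:
        if chrom not in self:
            raise KeyError(
                f"chromosome {chrom!r} absent from chrom-sizes table "
                f"(known: {sorted(self)})"
            )
        return self[chrom]


@dataclass
class GeneCluster:
    """A named gene set (e.g. up-regulated at FDR < 0.05), resolved against a universe."""

    name: str
    members: frozenset[str]
    n_unresolved: int = 0

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError(f"cluster {self.name!r} is empty; enrichment is undefined")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# readers / writers


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line), skipping headers and blanks."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            yield lineno, line


def read_bed(path: str | Path, kind: str = "peaks") -> list[GenomicInterval]:
    """Read a BED3/BED6 file into validated, sorted intervals.

    ``kind`` is ``"peaks"`` or ``"domains"``; for domains a missing name column
    is filled with a positional id so every domain is addressable.  Output is
    sorted by (chrom, start, end) regardless of input order.
    """
    if kind not in ("peaks", "domains"):
        raise ValueError(f"kind must be 'peaks' or 'domains', got {kind!r}")
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        if name is None and kind == "domains":
            name = f"{chrom}:{start}-{end}"
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    intervals.sort(key=GenomicInterval.sort_key)
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; emits exactly the columns needed to round-trip."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_extra = iv.name is not None or iv.score is not None or iv.strand != "."
            if has_extra:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                fields.append(_fmt_score(iv.score))
            if iv.strand != ".":
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_genes(path: str | Path) -> list[GeneRecord]:
    """Read a BED6-like gene table (chrom, start, end, gene_id, score, strand).

    One row per gene with a pre-resolved TSS-defining interval; the strand
    column is mandatory and duplicate gene ids are an error.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(
                f"{path}:{lineno}: gene table needs 6 columns (chrom, start, end, id, score, strand)"
            )
        chrom, gene_id, strand = fields[0], fields[3], fields[5]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: gene strand must be + or -, got {strand!r}")
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        try:
            start, end = int(fields[1]), int(fields[2])
            score = None if fields[4] == "." else float(fields[4])
            interval = GenomicInterval(chrom, start, end, name=gene_id, score=score, strand=strand)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        genes.append(GeneRecord(gene_id, interval))
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def write_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            score = _fmt_score(iv.score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t{score}\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns (chrom, length)")
        try:
            length = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer length") from exc
        if fields[0] in sizes:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
        sizes[fields[0]] = length
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_cluster(path: str | Path, universe: Iterable[str], name: str | None = None) -> GeneCluster:
    """Read a newline-delimited gene-id list and resolve it against a universe.

    Ids absent from the universe are dropped (counted in ``n_unresolved`` and
    logged); an empty intersection raises, since enrichment of nothing is
    undefined.
    """
    universe_set = set(universe)
    ids: list[str] = []
    with open(path) as fh:
        for raw in fh:
            token = raw.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    members = frozenset(i for i in ids if i in universe_set)
    dropped = len(set(ids)) - len(members)
    cluster_name = name if name is not None else Path(path).stem
    if dropped:
        log.warning("cluster %s: dropped %d ids absent from the gene universe", cluster_name, dropped)
    if not members:
        raise FormatError(
            f"cluster {cluster_name!r}: none of {len(set(ids))} ids resolve against the gene universe"
        )
    return GeneCluster(cluster_name, members, n_unresolved=dropped)


def write_cluster(cluster: GeneCluster, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(cluster.members):
            fh.write(gene_id + "\n")


def check_chrom_namespaces(named_sets: Mapping[str, Iterable[str]]) -> None:
    """Hard-error when files use disjoint chromosome namespaces (e.g. chr1 vs 1).

    ``named_sets`` maps a file label to the chromosome names it uses.  Any pair
    of non-empty sets with an empty intersection is reported; partial overlap
    (extra chromosomes in one file) is allowed.
    """
    items = [(label, set(chroms)) for label, chroms in named_sets.items() if chroms]
    problems = []
    for i, (label_a, set_a) in enumerate(items):
        for label_b, set_b in items[i + 1 :]:
            if not (set_a & set_b):
                problems.append(
                    f"{label_a} (e.g. {sorted(set_a)[:3]}) shares no chromosome names "
                    f"with {label_b} (e.g. {sorted(set_b)[:3]})"
                )
    if problems:
        raise FormatError("chromosome namespace mismatch: " + "; ".join(problems))
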