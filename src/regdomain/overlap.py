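"""Anchored interval intersection and n-way cistrome overlap partitioning.

Anchored intersection is asymmetric (bedtools ``-u`` semantics): the result
reports intervals of the *anchor* set A, with their original coordinates, that
overlap by at least 1 bp any interval of the query set B.  Overlap is tested
under half-open coordinates, so book-ended intervals (``end == start``) never
overlap.  The anchor direction is explicit in every function signature here
and recorded in pipeline output metadata, because counts differ when the
direction flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts sorted ascending, running max of ends) arrays."""
    chroms: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        chroms.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, pairs in chroms.items():
        pairs.sort()
        starts = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
        ends = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        out[chrom] = (starts, np.maximum.accumulate(ends))
    return out


def overlap_flags(anchor: Sequence[GenomicInterval], query: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean flag per anchor interval: does it overlap >= 1 bp of the query set?

    Sorted-start + running-max-of-ends search: an anchor [s, e) overlaps some
    query interval iff among query intervals with start < e the maximum end
    exceeds s.  O((|A| + |B|) log |B|).
    """
    index = _by_chrom(query)
    flags = np.zeros(len(anchor), dtype=bool)
    for i, iv in enumerate(anchor):
        entry = index.get(iv.chrom)
        if entry is None:
            continue
        starts, running_max_end = entry
        j = int(np.searchsorted(starts, iv.end, side="left"))  # starts[:j] < end
        flags[i] = j > 0 and running_max_end[j - 1] > iv.start
    return flags


def intersect_anchored(
    anchor: Sequence[GenomicInterval], query: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intervals of ``anchor`` overlapping >= 1 bp of ``query``, original coordinates, order preserved."""
    flags = overlap_flags(anchor, query)
    return [iv for iv, f in zip(anchor, flags) if f]


def consensus(
    primary: Sequence[GenomicInterval], others: Sequence[Sequence[GenomicInterval]]
) -> list[GenomicInterval]:
    """Consensus peaks: intervals of ``primary`` overlapping every set in ``others``.

    This is the multi-background consensus step used to derive a
    high-confidence cistrome from peak calls made against several background
    datasets; the count is anchored on ``primary`` and |result| <= |primary|.
    """
    if not others:
        raise ValueError("consensus requires at least one comparison peak set")
    result = list(primary)
    for other in others:
        result = intersect_anchored(result, other)
    return result


_CATEGORIES = ("only", "and_second", "and_third", "all_three")


@dataclass
class ThreeWayPartition:
    """Per-set anchored partition of three cistromes (a Venn-style breakdown).

    Each interval of each input set falls in exactly one of four categories
    determined by anchored overlap against the other two sets, e.g. for set A:
    A-only, A∩B-only, A∩C-only, A∩B∩C.  Counts within a set always sum to that
    set's size.  Because overlap is anchored, the A∩B count measured from A may
    differ from the one measured from B; both are reported.
    """

    labels: tuple[str, str, str]
    parts: dict[str, dict[str, list[GenomicInterval]]]

    def counts(self) -> pd.DataFrame:
        rows = []
        for label in self.labels:
            others = [l for l in self.labels if l != label]
            pretty = {
                "only": f"{label}_only",
                "and_second": f"{label}_and_{others[0]}",
                "and_third": f"{label}_and_{others[1]}",
                "all_three": f"{label}_and_{others[0]}_and_{others[1]}",
            }
            for cat in _CATEGORIES:
                rows.append(
                    {
                        "anchor_set": label,
                        "category": pretty[cat],
                        "count": len(self.parts[label][cat]),
                    }
                )
        return pd.DataFrame(rows)


def partition_three_way(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    c: Sequence[GenomicInterval],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> ThreeWayPartition:
    """Assign every interval of each set to its anchored-overlap category.

    Mirrors a three-set Venn of cistromes (shared sites, pairwise-only sites,
    set-private sites) while keeping each set's own coordinates.
    """
    sets = {labels[0]: list(a), labels[1]: list(b), labels[2]: list(c)}
    order = list(labels)
    parts: dict[str, dict[str, list[GenomicInterval]]] = {}
    for label in order:
        others = [l for l in order if l != label]
        own = sets[label]
        f1 = overlap_flags(own, sets[others[0]])
        f2 = overlap_flags(own, sets[others[1]])
        cats: dict[str, list[GenomicInterval]] = {cat: [] for cat in _CATEGORIES}
        for iv, in_1, in_2 in zip(own, f1, f2):
            if in_1 and in_2:
                cats["all_three"].append(iv)
            elif in_1:
                cats["and_second"].append(iv)
            elif in_2:
                cats["and_third"].append(iv)
            else:
                cats["only"].append(iv)
        parts[label] = cats
    return ThreeWayPartition(labels=tuple(order), parts=parts)
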