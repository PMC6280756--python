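"""Genomic interval arithmetic in 0-based, half-open (BED) coordinates.

All region coordinates in the package — peaks, DRREs, exons, clusters,
reference open regions, alignment masks — live in this convention.  GTF
input (1-based, inclusive) is converted at parse time by :mod:`drre_kit.io`.
Book-ended intervals (``a.end == b.start``) merge, matching BEDOPS union
semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "overlaps",
    "merge_intervals",
    "span",
    "RegionSet",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open abutment ([0,10) vs [10,20)) does not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list.

    Book-ended intervals are merged: {[10,20), [20,25)} -> {[10,25)}.
    Idempotent and order-invariant.
    """
    items = sorted(intervals)
    merged: List[GenomicInterval] = []
    for iv in items:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def span(intervals: Sequence[GenomicInterval]) -> GenomicInterval:
    """Smallest single interval covering all inputs (one chromosome only)."""
    if not intervals:
        raise ValueError("span of empty interval collection")
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) != 1:
        raise ValueError(f"span across chromosomes: {sorted(chroms)}")
    return GenomicInterval(
        intervals[0].chrom,
        min(iv.start for iv in intervals),
        max(iv.end for iv in intervals),
    )


class RegionSet:
    """An immutable set of disjoint regions supporting fast overlap queries.

    Backed by per-chromosome sorted start/end arrays; intended for open-region
    collections (control/L3 open chromatin, FAIRE references, alignment masks,
    STARR-seq activity regions).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        merged = merge_intervals(intervals)
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        self._intervals = merged
        for iv in merged:
            self._by_chrom.setdefault(iv.chrom, ([], []))  # type: ignore[arg-type]
        starts: Dict[str, List[int]] = {c: [] for c in self._by_chrom}
        ends: Dict[str, List[int]] = {c: [] for c in self._by_chrom}
        for iv in merged:
            starts[iv.chrom].append(iv.start)
            ends[iv.chrom].append(iv.end)
        self._by_chrom = {
            c: (np.asarray(starts[c], dtype=np.int64), np.asarray(ends[c], dtype=np.int64))
            for c in starts
        }

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    @property
    def intervals(self) -> List[GenomicInterval]:
        return list(self._intervals)

    def overlaps(self, iv: GenomicInterval) -> bool:
        """True iff ``iv`` shares >= 1 base with any region in the set."""
        arrs = self._by_chrom.get(iv.chrom)
        if arrs is None:
            return False
        starts, ends = arrs
        i = int(np.searchsorted(starts, iv.end, side="left"))
        # regions with start < iv.end; the nearest one to the left must end past iv.start
        return i > 0 and ends[i - 1] > iv.start

    def covered_bases(self, iv: GenomicInterval) -> int:
        """Number of bases of ``iv`` covered by the set."""
        arrs = self._by_chrom.get(iv.chrom)
        if arrs is None:
            return 0
        starts, ends = arrs
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], iv.start)
        e = np.minimum(ends[lo:hi], iv.end)
        return int(np.sum(e - s))
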