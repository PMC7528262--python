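"""Genomic interval primitives and interval arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)``.
External formats with other conventions are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval {self.chrom}:{self.start}-{self.end}")

    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap length in bp; 0 for different chromosomes or book-ended intervals."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, text: str) -> "GenomicInterval":
        chrom, _, span = text.rpartition(":")
        lo, _, hi = span.partition("-")
        if not chrom or not lo or not hi:
            raise ValueError(f"cannot parse interval id {text!r}")
        return cls(chrom, int(lo), int(hi))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of maximal disjoint intervals.

    Strictly overlapping intervals merge; book-ended ones (end == start) do not
    overlap under half-open semantics but are still coalesced here because the
    union of their positions is contiguous.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length() for iv in merge_intervals(intervals))


def intersect_unions(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two interval unions (inputs need not be disjoint)."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        x, y = am[i], bm[j]
        if x.chrom != y.chrom:
            if (x.chrom, x.start) < (y.chrom, y.start):
                i += 1
            else:
                j += 1
            continue
        piece = x.intersect(y)
        if piece is not None:
            out.append(piece)
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Positions in the union of ``a`` not covered by the union of ``b``."""
    result: list[GenomicInterval] = []
    bm = merge_intervals(b)
    for iv in merge_intervals(a):
        cursor = iv.start
        for cut in bm:
            if cut.chrom != iv.chrom or cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                result.append(GenomicInterval(iv.chrom, cursor, cut.start))
            cursor = max(cursor, cut.end)
        if cursor < iv.end:
            result.append(GenomicInterval(iv.chrom, cursor, iv.end))
    return result
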