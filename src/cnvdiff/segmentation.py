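"""CNVR dissection into boundary-consistent segments and per-sample genotyping.

Segments are cut at the union of member-call breakpoints so every individual
is genotyped over the exact same intervals; a segment's genotype is the copy
class of a confident call fully containing it, defaulting to diploid (2).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .call_integration import CNVR, ConfidentCall
from .intervals import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

DIPLOID_CLASS = 2


@dataclass(frozen=True)
class Segment:
    interval: GenomicInterval
    parent_cnvr: GenomicInterval | None = None

    @property
    def segment_id(self) -> str:
        return self.interval.id


@dataclass
class SegmentGenotypeMatrix:
    """Segments x samples matrix of copy-number classes in {0,1,2,3,4}."""

    segments: list[Segment]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype="int8")
        if self.values.shape != (len(self.segments), len(self.samples)):
            raise ValueError("matrix shape does not match segments x samples")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 4):
            raise ValueError("genotype classes must lie in {0,1,2,3,4}")

    @property
    def segment_ids(self) -> list[str]:
        return [s.segment_id for s in self.segments]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.segment_ids, columns=self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentGenotypeMatrix):
            return NotImplemented
        return (
            self.segment_ids == other.segment_ids
            and self.samples == other.samples
            and np.array_equal(self.values, other.values)
        )


def dissect_segments(
    cnvr: CNVR | GenomicInterval,
    member_calls: Sequence[ConfidentCall],
    min_len: int = 50,
) -> list[Segment]:
    """Cut a CNVR at the union of member-call breakpoints.

    Candidate segments run between consecutive breakpoints restricted to
    positions covered by at least one call; segments of length <= ``min_len``
    are dropped (the length filter is strict).
    """
    region = cnvr.interval if isinstance(cnvr, CNVR) else cnvr
    clipped = []
    for call in member_calls:
        piece = region.intersect(call.interval)
        if piece is None:
            raise ValueError(f"call {call.interval.id} does not overlap CNVR {region.id}")
        clipped.append(piece)
    breakpoints = sorted({p for iv in clipped for p in (iv.start, iv.end)})
    covered = merge_intervals(clipped)
    segments: list[Segment] = []
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        if hi - lo <= min_len:
            continue
        if any(c.start <= lo and hi <= c.end for c in covered):
            segments.append(Segment(GenomicInterval(region.chrom, lo, hi), parent_cnvr=region))
    return segments


def assign_calls_to_cnvrs(
    cnvrs: Sequence[CNVR], calls: Sequence[ConfidentCall]
) -> dict[int, list[ConfidentCall]]:
    """Map CNVR index -> confident calls overlapping it (CNVRs are disjoint)."""
    by_chrom: dict[str, list[tuple[int, CNVR]]] = defaultdict(list)
    for i, r in enumerate(cnvrs):
        by_chrom[r.interval.chrom].append((i, r))
    for group in by_chrom.values():
        group.sort(key=lambda t: t[1].interval)
    assigned: dict[int, list[ConfidentCall]] = defaultdict(list)
    for chrom, group in by_chrom.items():
        starts = [r.interval.start for _, r in group]
        chrom_calls = sorted(
            (c for c in calls if c.interval.chrom == chrom), key=lambda c: c.interval
        )
        j = 0
        for call in chrom_calls:
            while j < len(group) and group[j][1].interval.end <= call.interval.start:
                j += 1
            for idx, r in group[j:]:
                if r.interval.start >= call.interval.end:
                    break
                if r.interval.overlaps(call.interval):
                    assigned[idx].append(call)
        del starts
    return assigned


def dissect_all(
    cnvrs: Sequence[CNVR], calls: Sequence[ConfidentCall], min_len: int = 50
) -> list[Segment]:
    """Dissect every CNVR against the calls overlapping it; concatenated, sorted."""
    assigned = assign_calls_to_cnvrs(cnvrs, calls)
    segments: list[Segment] = []
    for i, cnvr in enumerate(cnvrs):
        segments.extend(dissect_segments(cnvr, assigned.get(i, []), min_len=min_len))
    segments.sort(key=lambda s: s.interval)
    return segments


def _pick_class(classes: list[int]) -> int:
    # precedence: farthest from diploid, ties broken toward the lower class
    return min(classes, key=lambda c: (-abs(c - DIPLOID_CLASS), c))


def genotype_segments(
    segments: Sequence[Segment],
    confident_calls: Sequence[ConfidentCall],
    samples: Sequence[str],
) -> SegmentGenotypeMatrix:
    """Genotype every sample at every segment.

    A sample's genotype at a segment is the copy class of a confident call
    fully containing the segment; with no such call the sample is diploid
    (class 2). Conflicting fully-covering calls resolve to the class farthest
    from 2 (ties to the lower class) and are logged.
    """
    samples = list(samples)
    col = {s: j for j, s in enumerate(samples)}
    values = np.full((len(segments), len(samples)), DIPLOID_CLASS, dtype="int8")

    by_key: dict[tuple[str, str], list[ConfidentCall]] = defaultdict(list)
    for call in confident_calls:
        if call.sample_id not in col:
            raise ValueError(f"call sample {call.sample_id!r} not in sample list")
        by_key[(call.sample_id, call.interval.chrom)].append(call)
    for group in by_key.values():
        group.sort(key=lambda c: c.interval)

    order = sorted(range(len(segments)), key=lambda i: segments[i].interval)
    conflicts = 0
    for (sample_id, chrom), group in by_key.items():
        j = col[sample_id]
        active: list[ConfidentCall] = []
        k = 0
        for i in order:
            seg = segments[i].interval
            if seg.chrom != chrom:
                continue
            while k < len(group) and group[k].interval.start <= seg.start:
                active.append(group[k])
                k += 1
            active = [c for c in active if c.interval.end > seg.start]
            covering = [c.copy_class for c in active if c.interval.end >= seg.end]
            if covering:
                if len(set(covering)) > 1:
                    conflicts += 1
                values[i, j] = _pick_class(covering)
    if conflicts:
        logger.info("resolved %d conflicting fully-covering genotype calls", conflicts)
    return SegmentGenotypeMatrix(segments=list(segments), samples=samples, values=values)


def segment_frequency(matrix: SegmentGenotypeMatrix) -> np.ndarray:
    """Per-segment variant frequency: fraction of samples with class != 2."""
    if not matrix.samples:
        raise ValueError("genotype matrix has zero samples")
    return (matrix.values != DIPLOID_CLASS).mean(axis=1)


def high_frequency_segments(
    matrix: SegmentGenotypeMatrix, threshold: float = 0.5
) -> list[Segment]:
    """Segments whose variant frequency is >= threshold (inclusive)."""
    freq = segment_frequency(matrix)
    return [seg for seg, f in zip(matrix.segments, freq) if f >= threshold]
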