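"""Dual-caller call integration: confident calls, distinct CNVs, CNVRs.

A confident call is a boundary-caller call corroborated by a same-type
depth-caller call; its interval comes from the boundary caller (single-base
breakpoint resolution) and its integer copy-number class from the depth
caller's normalized read depth.
"""

from __future__ import annotations

import bisect
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .io_formats import BOUNDARY_CALLER, DEPTH_CALLER, GAIN, LOSS, RawCall, SampleTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfidentCall:
    sample_id: str
    interval: GenomicInterval
    cnv_type: Literal["loss", "gain"]
    copy_class: int  # 4 encodes ">=4"

    def __post_init__(self) -> None:
        if not 0 <= self.copy_class <= 4:
            raise ValueError(f"copy_class {self.copy_class} outside [0,4]")
        if self.cnv_type == LOSS and self.copy_class >= 2:
            raise ValueError("loss calls must have copy_class < 2")
        if self.cnv_type == GAIN and self.copy_class <= 2:
            raise ValueError("gain calls must have copy_class > 2")


@dataclass
class DistinctCNV:
    interval: GenomicInterval
    cnv_type: str
    supporting_samples: set[str]


@dataclass
class CNVR:
    interval: GenomicInterval
    member_cnvs: list[DistinctCNV]
    region_type: Literal["loss", "gain", "mixed"]
    supporting_samples: set[str]
    supporting_breeds: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class IntersectPolicy:
    """Overlap requirements for accepting a boundary call as confident."""

    min_overlap_bp: int = 1
    reciprocal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_overlap_bp < 0 or self.reciprocal_fraction < 0:
            raise ValueError("policy thresholds must be >= 0")


def copy_class_from_depth(normalized_depth: float, cnv_type: str) -> int:
    """Map normalized read depth (1.0 ~ diploid) to the class set {0,1,2,3,4}.

    round(2 * depth), half-up, clamped to [0, 4]; then forced onto the side of
    2 consistent with the call type so class and type can never disagree.
    """
    c = min(4, max(0, math.floor(2.0 * normalized_depth + 0.5)))
    if cnv_type == LOSS:
        return min(c, 1)
    return max(c, 3)


def intersect_calls(
    boundary_calls: Sequence[RawCall],
    depth_calls: Sequence[RawCall],
    policy: IntersectPolicy = IntersectPolicy(),
) -> list[ConfidentCall]:
    """Corroborate one sample's boundary-caller calls against its depth calls.

    A boundary call becomes confident when at least one same-type depth call
    overlaps it by ``min_overlap_bp`` (and by ``reciprocal_fraction`` of both
    lengths, when set). The copy class is taken from the supporting depth call
    with the largest overlap; ties prefer the depth call whose endpoints are
    closest to the boundary call's. One depth call may support several
    boundary calls.
    """
    samples = {c.sample_id for c in boundary_calls} | {c.sample_id for c in depth_calls}
    if len(samples) > 1:
        raise ValueError(f"intersect_calls is per-sample; got samples {sorted(samples)}")
    for c in boundary_calls:
        if c.source != BOUNDARY_CALLER:
            raise ValueError("boundary_calls must have source=boundary_caller")
    for c in depth_calls:
        if c.source != DEPTH_CALLER:
            raise ValueError("depth_calls must have source=depth_caller")

    by_key: dict[tuple[str, str], list[RawCall]] = defaultdict(list)
    for d in depth_calls:
        by_key[(d.interval.chrom, d.cnv_type)].append(d)
    index: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for key, group in by_key.items():
        group.sort(key=lambda c: c.interval)
        starts = [c.interval.start for c in group]
        max_ends: list[int] = []
        running = 0
        for c in group:
            running = max(running, c.interval.end)
            max_ends.append(running)
        index[key] = (starts, max_ends)

    out: list[ConfidentCall] = []
    for b in sorted(boundary_calls, key=lambda c: c.interval):
        best: tuple[int, int, RawCall] | None = None  # (overlap, -endpoint distance, call)
        group = by_key.get((b.interval.chrom, b.cnv_type), [])
        starts, max_ends = index.get((b.interval.chrom, b.cnv_type), ([], []))
        # candidates: start < b.end and end > b.start; scan backwards from the
        # last start before b.end, pruned by the running max of ends
        i = bisect.bisect_left(starts, b.interval.end) - 1
        while i >= 0 and max_ends[i] > b.interval.start:
            d = group[i]
            i -= 1
            ov = b.interval.overlap_bp(d.interval)
            if ov < max(1, policy.min_overlap_bp):
                continue
            if policy.reciprocal_fraction > 0 and (
                ov < policy.reciprocal_fraction * b.interval.length()
                or ov < policy.reciprocal_fraction * d.interval.length()
            ):
                continue
            dist = abs(d.interval.start - b.interval.start) + abs(d.interval.end - b.interval.end)
            rank = (ov, -dist, -d.interval.start, -d.interval.end)
            if best is None or rank > best[:4]:
                best = (*rank, d)
        if best is not None:
            out.append(
                ConfidentCall(
                    sample_id=b.sample_id,
                    interval=b.interval,
                    cnv_type=b.cnv_type,
                    copy_class=copy_class_from_depth(best[4].normalized_depth, b.cnv_type),
                )
            )
    return out


def collapse_distinct(confident_calls: Iterable[ConfidentCall]) -> list[DistinctCNV]:
    """Collapse calls identical in (chrom, start, end, type) across samples."""
    groups: dict[tuple[GenomicInterval, str], set[str]] = defaultdict(set)
    for call in confident_calls:
        groups[(call.interval, call.cnv_type)].add(call.sample_id)
    return [
        DistinctCNV(interval=iv, cnv_type=t, supporting_samples=samples)
        for (iv, t), samples in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]


def build_cnvrs(
    distinct_cnvs: Sequence[DistinctCNV],
    min_support: int = 4,
    sample_table: SampleTable | None = None,
) -> list[CNVR]:
    """Single-linkage merge of distinct CNVs into CNVRs, type-blind.

    Any >=1 bp overlap chains CNVs into one region; book-ended intervals
    (end == start) do not merge. Regions supported by fewer than
    ``min_support`` distinct samples are discarded.
    """
    cnvrs: list[CNVR] = []
    for chrom in sorted({c.interval.chrom for c in distinct_cnvs}):
        members: list[DistinctCNV] = []
        span_end = -1
        chrom_cnvs = sorted(
            (c for c in distinct_cnvs if c.interval.chrom == chrom), key=lambda c: c.interval
        )

        def flush() -> None:
            if not members:
                return
            types = {m.cnv_type for m in members}
            region_type = members[0].cnv_type if len(types) == 1 else "mixed"
            samples: set[str] = set()
            for m in members:
                samples |= m.supporting_samples
            breeds = (
                {sample_table.breed_of(s) for s in samples} if sample_table is not None else set()
            )
            cnvrs.append(
                CNVR(
                    interval=GenomicInterval(chrom, members[0].interval.start, span_end),
                    member_cnvs=list(members),
                    region_type=region_type,
                    supporting_samples=samples,
                    supporting_breeds=breeds,
                )
            )

        for cnv in chrom_cnvs:
            if members and cnv.interval.start < span_end:
                members.append(cnv)
                span_end = max(span_end, cnv.interval.end)
            else:
                flush()
                members = [cnv]
                span_end = cnv.interval.end
        flush()
    kept = [r for r in cnvrs if len(r.supporting_samples) >= min_support]
    logger.info("built %d CNVRs, kept %d with support >= %d", len(cnvrs), len(kept), min_support)
    return kept


# ---------------------------------------------------------------------------
# confident-call TSV persistence (CLI interchange format)
# ---------------------------------------------------------------------------

CALLS_COLUMNS = ["sample_id", "chrom", "start", "end", "cnv_type", "copy_class"]


def write_calls_tsv(calls: Sequence[ConfidentCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.sample_id, c.interval.chrom, c.interval.start, c.interval.end, c.cnv_type, c.copy_class)
            for c in calls
        ],
        columns=CALLS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list[ConfidentCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    return [
        ConfidentCall(
            sample_id=row.sample_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            cnv_type=row.cnv_type,
            copy_class=int(row.copy_class),
        )
        for row in df.itertuples(index=False)
    ]
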