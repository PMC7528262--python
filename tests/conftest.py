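"""Shared fixtures and independent brute-force oracles.

Oracles deliberately avoid the package's interval machinery: they enumerate
per-base numpy arrays or use union-find over the pairwise-overlap graph, so
they stay independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cnvdiff.call_integration import CNVR, ConfidentCall, DistinctCNV
from cnvdiff.intervals import GenomicInterval
from cnvdiff.io_formats import SampleTable


# ---------------------------------------------------------------------------
# small builders
# ---------------------------------------------------------------------------

def iv(chrom: str, start: int, end: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


def make_cnvr(chrom, start, end, samples=("s1", "s2", "s3", "s4"), region_type="loss"):
    region = GenomicInterval(chrom, start, end)
    return CNVR(
        interval=region,
        member_cnvs=[DistinctCNV(region, region_type if region_type != "mixed" else "loss",
                                 set(samples))],
        region_type=region_type,
        supporting_samples=set(samples),
    )


def make_call(sample, chrom, start, end, cnv_type="loss", copy_class=None):
    if copy_class is None:
        copy_class = 1 if cnv_type == "loss" else 3
    return ConfidentCall(sample, GenomicInterval(chrom, start, end), cnv_type, copy_class)


@pytest.fixture
def sample_table() -> SampleTable:
    return SampleTable(
        [
            ("t1", "Angus", "taurine"),
            ("t2", "Angus", "taurine"),
            ("t3", "NDama", "taurine"),
            ("i1", "Nelore", "indicine"),
            ("i2", "Nelore", "indicine"),
            ("i3", "Gir", "indicine"),
        ]
    )


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_union_find_merge(cnvs: list[DistinctCNV]) -> list[tuple[str, int, int, set[str]]]:
    """Single-linkage merge via union-find over the pairwise >=1bp-overlap graph."""
    n = len(cnvs)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n):
        for b in range(a + 1, n):
            x, y = cnvs[a].interval, cnvs[b].interval
            if x.chrom == y.chrom and min(x.end, y.end) - max(x.start, y.start) > 0:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), []).append(k)
    out = []
    for members in groups.values():
        ivs = [cnvs[m].interval for m in members]
        samples: set[str] = set()
        for m in members:
            samples |= cnvs[m].supporting_samples
        out.append(
            (ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs), samples)
        )
    return sorted(out, key=lambda t: (t[0], t[1]))


def perbase_cover(intervals, length: int, chrom: str | None = None) -> np.ndarray:
    """Boolean per-base occupancy array for a single chromosome."""
    cover = np.zeros(length, dtype=bool)
    for v in intervals:
        if chrom is not None and v.chrom != chrom:
            continue
        cover[v.start : v.end] = True
    return cover


def random_intervals(rng, chrom: str, genome_len: int, n: int, max_len: int):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, genome_len - 1))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(chrom, start, min(start + length, genome_len)))
    return out
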