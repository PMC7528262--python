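"""Per-segment F_ST between two populations of copy-number genotypes.

The statistic is computed over individual genotype-class frequencies
(classes 0,1,2,3,4 with 4 meaning ">=4"):

    t_i = (x_i*Nx + y_i*Ny) / (Nx + Ny)
    Ht  = 1 - sum_i t_i^2
    Hs  = ((1 - sum_i x_i^2)*Nx + (1 - sum_i y_i^2)*Ny) / (Nx + Ny)
    F_ST = (Ht - Hs) / Ht        (0 when Ht == 0)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_formats import SampleTable
from .segmentation import DIPLOID_CLASS, SegmentGenotypeMatrix

CLASSES = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class ClassFrequencies:
    """Genotype-class frequency spectrum of one population at one segment."""

    label: str
    n: int
    freq: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be >= 1")
        if len(self.freq) != len(CLASSES):
            raise ValueError(f"need {len(CLASSES)} class frequencies")
        if any(f < 0 or f > 1 for f in self.freq):
            raise ValueError("frequencies must lie in [0,1]")
        if abs(sum(self.freq) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


@dataclass(frozen=True)
class FstRecord:
    segment_id: str
    x: ClassFrequencies
    y: ClassFrequencies
    t: tuple[float, ...]
    ht: float
    hs: float
    fst: float


def _resolve_samples(
    sample_table: SampleTable, selector: str | Callable[[str], bool] | Sequence[str]
) -> list[str]:
    if callable(selector):
        return [s for s in sample_table.samples if selector(s)]
    if isinstance(selector, str):
        return sample_table.samples_in(selector)
    return list(selector)


def class_frequencies(
    matrix: SegmentGenotypeMatrix,
    sample_table: SampleTable,
    selector: str | Callable[[str], bool] | Sequence[str],
    label: str | None = None,
) -> list[ClassFrequencies]:
    """Per-segment genotype-class frequencies over the selected samples."""
    selected = _resolve_samples(sample_table, selector)
    if not selected:
        raise ValueError("population selector matched no samples")
    missing = set(selected) - set(matrix.samples)
    if missing:
        raise ValueError(f"selected samples absent from matrix: {sorted(missing)}")
    label = label if label is not None else (selector if isinstance(selector, str) else "population")
    cols = [matrix.samples.index(s) for s in selected]
    sub = matrix.values[:, cols]
    n = len(cols)
    counts = np.stack([(sub == c).sum(axis=1) for c in CLASSES], axis=1)
    freqs = counts / n
    return [ClassFrequencies(label=label, n=n, freq=tuple(row)) for row in freqs]


def compute_fst(
    x: ClassFrequencies, y: ClassFrequencies, segment_id: str = ""
) -> FstRecord:
    """Evaluate the weighted-heterozygosity F_ST between two populations."""
    nx, ny = x.n, y.n
    t = tuple((xi * nx + yi * ny) / (nx + ny) for xi, yi in zip(x.freq, y.freq))
    ht = 1.0 - sum(ti * ti for ti in t)
    hx = 1.0 - sum(xi * xi for xi in x.freq)
    hy = 1.0 - sum(yi * yi for yi in y.freq)
    hs = (hx * nx + hy * ny) / (nx + ny)
    fst = 0.0 if ht <= 0.0 else (ht - hs) / ht
    # guard numerical noise at the boundaries
    fst = min(1.0, max(0.0, fst))
    return FstRecord(segment_id=segment_id, x=x, y=y, t=t, ht=ht, hs=hs, fst=fst)


def fst_scan(
    matrix: SegmentGenotypeMatrix,
    sample_table: SampleTable,
    pop_x: str = "taurine",
    pop_y: str = "indicine",
) -> list[FstRecord]:
    """Per-segment F_ST between two subspecies (pooled individuals)."""
    fx = class_frequencies(matrix, sample_table, pop_x)
    fy = class_frequencies(matrix, sample_table, pop_y)
    return [
        compute_fst(x, y, segment_id=sid)
        for sid, x, y in zip(matrix.segment_ids, fx, fy)
    ]


def rank_segments(fst_records: Sequence[FstRecord], top_fraction: float) -> list[FstRecord]:
    """Top-percentile segments by F_ST, descending; ties at the cut included."""
    if not fst_records:
        raise ValueError("no F_ST records to rank")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0,1)")
    ranked = sorted(fst_records, key=lambda r: (-r.fst, r.segment_id))
    k = math.ceil(top_fraction * len(ranked))
    cut = ranked[k - 1].fst
    while k < len(ranked) and ranked[k].fst == cut:
        k += 1
    return ranked[:k]


def status_rates(
    matrix: SegmentGenotypeMatrix, sample_table: SampleTable
) -> pd.DataFrame:
    """Loss/normal/gain proportions per (segment, subspecies).

    Loss is class < 2, normal == 2, gain > 2; the three proportions sum to 1.
    """
    rows = []
    for pop in sample_table.subspecies:
        cols = [matrix.samples.index(s) for s in sample_table.samples_in(pop)]
        sub = matrix.values[:, cols]
        n = len(cols)
        rows.append(
            pd.DataFrame(
                {
                    "segment_id": matrix.segment_ids,
                    "population": pop,
                    "loss": (sub < DIPLOID_CLASS).sum(axis=1) / n,
                    "normal": (sub == DIPLOID_CLASS).sum(axis=1) / n,
                    "gain": (sub > DIPLOID_CLASS).sum(axis=1) / n,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def pca_coordinates(matrix: SegmentGenotypeMatrix, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto principal axes of the centered genotype matrix.

    Deterministic up to sign; signs are fixed so the largest-magnitude loading
    of each component is positive.
    """
    if len(matrix.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    data = matrix.values.T.astype(float)  # samples x segments
    data -= data.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds matrix rank {rank}")
    coords = u[:, :n_components] * s[:n_components]
    for j in range(n_components):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords,
        index=matrix.samples,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
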