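"""Genome-level summaries of CNVRs: gene overlap, feature-class enrichment,
window density and clusters, breed/subspecies sharing, and specific sequences.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .call_integration import CNVR
from .intervals import GenomicInterval, intersect_unions, merge_intervals, union_length
from .io_formats import FEATURE_CLASSES, FeatureSet, SampleTable


@dataclass(frozen=True)
class WindowDensity:
    window: GenomicInterval
    covered_bp: int

    @property
    def covered_fraction(self) -> float:
        return self.covered_bp / self.window.length()


@dataclass
class SharingSummary:
    breeds_per_cnvr: list[frozenset[str]]
    subspecies_per_cnvr: list[frozenset[str]]
    pattern_counts: Counter

    @property
    def all_breeds(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for b in self.breeds_per_cnvr:
            out |= b
        return out


def _cnvr_union(cnvrs: Sequence[CNVR]) -> list[GenomicInterval]:
    return merge_intervals(r.interval for r in cnvrs)


def overlap_genes(
    cnvrs: Sequence[CNVR],
    features: FeatureSet,
    min_overlap_bp: int = 1,
) -> tuple[set[str], set[str]]:
    """Genes touched by CNVRs, and the subset touched in an exon.

    Overlap of at least ``min_overlap_bp`` with any feature of the gene counts
    (default: a single bp).
    """
    union = _cnvr_union(cnvrs)
    genes: set[str] = set()
    exon_genes: set[str] = set()
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in union:
        by_chrom[iv.chrom].append(iv)
    for feat in features.features:
        ov = sum(feat.interval.overlap_bp(iv) for iv in by_chrom.get(feat.interval.chrom, ()))
        if ov >= min_overlap_bp:
            genes.add(feat.gene_id)
            if feat.feature_class == "exon":
                exon_genes.add(feat.gene_id)
    return genes, exon_genes


def feature_class_enrichment(
    cnvrs: Sequence[CNVR],
    features: FeatureSet,
    chrom_sizes: Mapping[str, int],
) -> dict[str, float]:
    """Observed/expected ratio of CNVR bp falling in each feature class.

    observed: fraction of total CNVR bp inside the class's interval union;
    expected: fraction of the genome (sum of chrom sizes) covered by the
    class. A class with zero genomic bp is an error.
    """
    union = _cnvr_union(cnvrs)
    total_cnvr_bp = union_length(union)
    genome_bp = sum(chrom_sizes.values())
    if total_cnvr_bp == 0:
        raise ValueError("no CNVR bp to evaluate")
    out: dict[str, float] = {}
    for cls in FEATURE_CLASSES:
        class_union = merge_intervals(features.by_class(cls))
        class_bp = union_length(class_union)
        if class_bp == 0:
            raise ValueError(f"feature class {cls!r} covers zero genomic bp")
        observed = union_length(intersect_unions(union, class_union)) / total_cnvr_bp
        expected = class_bp / genome_bp
        out[cls] = observed / expected
    return out


def window_density(
    cnvrs: Sequence[CNVR],
    chrom_sizes: Mapping[str, int],
    window: int = 1_000_000,
) -> list[WindowDensity]:
    """Tile each chromosome with nonoverlapping windows and measure CNVR cover.

    The terminal window of a chromosome may be short; its true length is the
    denominator of ``covered_fraction``.
    """
    union = _cnvr_union(cnvrs)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in union:
        by_chrom[iv.chrom].append(iv)
    densities: list[WindowDensity] = []
    for chrom, size in chrom_sizes.items():
        ivs = by_chrom.get(chrom, [])
        for start in range(0, size, window):
            win = GenomicInterval(chrom, start, min(start + window, size))
            covered = sum(win.overlap_bp(iv) for iv in ivs)
            densities.append(WindowDensity(window=win, covered_bp=covered))
    return densities


def detect_clusters(
    densities: Sequence[WindowDensity], threshold: float = 0.8
) -> list[GenomicInterval]:
    """Merge maximal runs of genome-adjacent windows with cover > threshold.

    The threshold is strict ("over 80%"): a window at exactly the threshold
    does not qualify.
    """
    qualifying = sorted(
        (d.window for d in densities if d.covered_fraction > threshold),
    )
    return merge_intervals(qualifying)


def breed_sharing(cnvrs: Sequence[CNVR], sample_table: SampleTable) -> SharingSummary:
    """Which breeds and subspecies support each CNVR, with pattern counts."""
    breeds_per = []
    subs_per = []
    patterns: Counter = Counter()
    for r in cnvrs:
        breeds = frozenset(sample_table.breed_of(s) for s in r.supporting_samples)
        subs = frozenset(sample_table.subspecies_of(s) for s in r.supporting_samples)
        breeds_per.append(breeds)
        subs_per.append(subs)
        patterns[breeds] += 1
    return SharingSummary(
        breeds_per_cnvr=breeds_per, subspecies_per_cnvr=subs_per, pattern_counts=patterns
    )


def shared_by_all(summary: SharingSummary, all_breeds: frozenset[str] | None = None) -> int:
    """Count CNVRs supported by every breed."""
    target = all_breeds if all_breeds is not None else summary.all_breeds
    return sum(1 for b in summary.breeds_per_cnvr if b == target)


def subspecies_comparison(
    cnvrs: Sequence[CNVR],
    sample_table: SampleTable,
    pop_x: str = "taurine",
    pop_y: str = "indicine",
) -> tuple[list[CNVR], list[CNVR], list[CNVR], float]:
    """Partition CNVRs into shared / X-specific / Y-specific sets.

    Returns ``(shared, x_specific, y_specific, shared_percentage)`` where the
    percentage is 100 * |shared| / |cnvrs| rounded to two decimals.
    """
    shared: list[CNVR] = []
    x_specific: list[CNVR] = []
    y_specific: list[CNVR] = []
    for r in cnvrs:
        subs = {sample_table.subspecies_of(s) for s in r.supporting_samples}
        if not subs:
            raise ValueError(f"CNVR {r.interval.id} has no supporting samples")
        if pop_x in subs and pop_y in subs:
            shared.append(r)
        elif pop_x in subs:
            x_specific.append(r)
        elif pop_y in subs:
            y_specific.append(r)
        else:
            raise ValueError(
                f"CNVR {r.interval.id} supported by neither {pop_x!r} nor {pop_y!r}"
            )
    pct = round(100.0 * len(shared) / len(cnvrs), 2) if cnvrs else 0.0
    return shared, x_specific, y_specific, pct


def specific_sequences(
    coverage_intervals: Sequence[tuple[GenomicInterval, float]],
    min_length: int = 500,
    min_depth: float = 2,
) -> tuple[list[GenomicInterval], int]:
    """Merge covered runs into candidate lineage-specific sequence intervals.

    Positions with depth >= ``min_depth`` (inclusive) are kept, adjacent and
    book-ended runs merged, and merged intervals longer than ``min_length``
    (strict) retained. Returns the intervals and their total bp.
    """
    for iv, depth in coverage_intervals:
        if depth < 0:
            raise ValueError(f"negative depth at {iv.id}")
    deep = [iv for iv, depth in coverage_intervals if depth >= min_depth]
    merged = merge_intervals(deep)
    kept = [iv for iv in merged if iv.length() > min_length]
    return kept, sum(iv.length() for iv in kept)
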