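"""Two-subspecies CNV call-set simulator with known truth.

Generates, for every animal, a paired call set: an exact-boundary call (the
split-read/paired-end dialect) and a depth call with jittered endpoints and a
noisy normalized read depth (the read-depth dialect). Planted events are
placed without mutual overlap so truth recovery is exact; noise truncation
guarantees the depth value still rounds to the true copy class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals
from .io_formats import (
    BOUNDARY_CALLER,
    DEPTH_CALLER,
    GAIN,
    LOSS,
    Feature,
    FeatureSet,
    RawCall,
    SampleTable,
    write_chrom_sizes,
    write_gff3,
    write_sample_table,
)

logger = logging.getLogger(__name__)

BACKGROUND = "background"
SHARED = "shared"
DIFFERENTIAL = "differential"

# event copy classes; 2 is reserved for non-carriers. Losses outweigh gains 2:1.
_EVENT_CLASSES = np.array([0, 1, 3, 4])
_EVENT_CLASS_WEIGHTS = np.array([2.0, 2.0, 1.0, 1.0]) / 6.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    chrom_count: int = 5
    chrom_length: int = 10_000_000
    breeds_per_subspecies: int = 2
    animals_per_breed: int = 5
    n_background_cnvs: int = 40
    n_shared_cnvrs: int = 150
    n_differential_segments: int = 1
    len_min: int = 500
    len_max: int = 5_000
    diff_loss_freq_x: float = 0.0
    diff_loss_freq_y: float = 1.0
    shared_carrier_prob: float = 0.6
    boundary_jitter_sd: float = 20.0
    depth_noise_sd: float = 0.05
    pop_x: str = "taurine"
    pop_y: str = "indicine"

    def __post_init__(self) -> None:
        if min(self.chrom_count, self.chrom_length, self.breeds_per_subspecies,
               self.animals_per_breed) <= 0:
            raise ValueError("genome and population dimensions must be positive")
        if min(self.n_background_cnvs, self.n_shared_cnvrs, self.n_differential_segments) < 0:
            raise ValueError("event counts must be >= 0")
        if not 0 < self.len_min <= self.len_max:
            raise ValueError("need 0 < len_min <= len_max")
        if self.boundary_jitter_sd < 0 or self.depth_noise_sd < 0:
            raise ValueError("jitter/noise sds must be >= 0")
        for f in (self.diff_loss_freq_x, self.diff_loss_freq_y, self.shared_carrier_prob):
            if not 0 <= f <= 1:
                raise ValueError("frequencies must lie in [0,1]")
        if self.n_shared_cnvrs > 0 and self.shared_carrier_prob == 0:
            raise ValueError("shared events need shared_carrier_prob > 0")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.chrom_count)}

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Parse a flat ``key value`` (or ``key=value``) config file."""
        kwargs: dict[str, object] = {}
        hints = cls.__dataclass_fields__
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.replace("=", " ").partition(" ")
            if key not in hints:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = hints[key].type
            value = value.strip()
            kwargs[key] = value if "str" in str(typ) else (
                float(value) if "float" in str(typ) else int(value)
            )
        if "seed" not in kwargs:
            raise ValueError(f"{path}: config must set seed")
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class PlantedEvent:
    interval: GenomicInterval
    label: str  # background | shared | differential
    cnv_type: str
    copy_class: int
    carriers: frozenset[str]


@dataclass
class SimulationTruth:
    events: list[PlantedEvent]
    sample_table: SampleTable
    chrom_sizes: dict[str, int]

    def events_with_support(self, min_support: int) -> list[PlantedEvent]:
        return [e for e in self.events if len(e.carriers) >= min_support]

    def true_class(self, event: PlantedEvent, sample_id: str) -> int:
        return event.copy_class if sample_id in event.carriers else 2


@dataclass
class SimulationResult:
    config: SimulationConfig
    sample_table: SampleTable
    chrom_sizes: dict[str, int]
    boundary_calls: dict[str, list[RawCall]]
    depth_calls: dict[str, list[RawCall]]
    truth: SimulationTruth


def _make_sample_table(config: SimulationConfig) -> SampleTable:
    rows = []
    for sub, prefix in ((config.pop_x, "X"), (config.pop_y, "Y")):
        for b in range(config.breeds_per_subspecies):
            breed = f"{prefix}breed{b + 1}"
            for a in range(config.animals_per_breed):
                rows.append((f"{breed}_a{a + 1}", breed, sub))
    return SampleTable(rows)


def _place_intervals(
    rng: np.random.Generator, config: SimulationConfig, lengths: Sequence[int]
) -> list[GenomicInterval]:
    """Walk the genome placing non-overlapping intervals with random gaps.

    Raises if the genome cannot hold all events; the caller never silently
    loses planted truth.
    """
    chroms = list(config.chrom_sizes.items())
    min_gap = 100
    # assign events to chromosomes, weighted by remaining capacity
    capacity = {c: size for c, size in chroms}
    assigned: dict[str, list[int]] = {c: [] for c, _ in chroms}
    for idx in rng.permutation(len(lengths)):
        need = int(lengths[int(idx)]) + min_gap
        fitting = [c for c, _ in chroms if capacity[c] >= need]
        if not fitting:
            raise ValueError("planted events exceed chromosome bounds; shrink counts or lengths")
        weights = np.array([capacity[c] for c in fitting], dtype=float)
        chosen = fitting[int(rng.choice(len(fitting), p=weights / weights.sum()))]
        assigned[chosen].append(int(idx))
        capacity[chosen] -= need
    # within each chromosome: sorted uniform offsets in the free space make the
    # placement exact — it cannot overflow
    placed: list[GenomicInterval | None] = [None] * len(lengths)
    for chrom, size in chroms:
        idxs = assigned[chrom]
        if not idxs:
            continue
        occupied = sum(int(lengths[i]) + min_gap for i in idxs)
        offsets = np.sort(rng.integers(0, size - occupied + 1, size=len(idxs)))
        cursor = 0
        for off, i in zip(offsets, idxs):
            start = int(off) + cursor + min_gap
            placed[i] = GenomicInterval(chrom, start, start + int(lengths[i]))
            cursor += int(lengths[i]) + min_gap
    return [iv for iv in placed if iv is not None]


def _pick_fixed_count(rng: np.random.Generator, pool: list[str], freq: float) -> set[str]:
    k = int(round(freq * len(pool)))
    if k == 0:
        return set()
    return set(rng.choice(pool, size=k, replace=False))


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate per-animal paired dual-caller call sets with known truth."""
    rng = np.random.default_rng(config.seed)
    table = _make_sample_table(config)
    pool_x = table.samples_in(config.pop_x)
    pool_y = table.samples_in(config.pop_y)
    all_samples = table.samples

    n_total = config.n_differential_segments + config.n_shared_cnvrs + config.n_background_cnvs
    lengths = np.exp(
        rng.uniform(np.log(config.len_min), np.log(config.len_max), size=n_total)
    ).astype(int)
    lengths = np.clip(lengths, config.len_min, config.len_max)
    intervals = _place_intervals(rng, config, lengths)
    order = rng.permutation(n_total)

    labels = (
        [DIFFERENTIAL] * config.n_differential_segments
        + [SHARED] * config.n_shared_cnvrs
        + [BACKGROUND] * config.n_background_cnvs
    )
    events: list[PlantedEvent] = []
    for slot, label in zip(order, labels):
        interval = intervals[int(slot)]
        if label == DIFFERENTIAL:
            carriers = _pick_fixed_count(rng, pool_x, config.diff_loss_freq_x) | _pick_fixed_count(
                rng, pool_y, config.diff_loss_freq_y
            )
            copy_class, cnv_type = 0, LOSS
        elif label == SHARED:
            while True:
                mask = rng.random(len(all_samples)) < config.shared_carrier_prob
                carriers = {s for s, m in zip(all_samples, mask) if m}
                if carriers & set(pool_x) and carriers & set(pool_y):
                    break
            copy_class = int(rng.choice(_EVENT_CLASSES, p=_EVENT_CLASS_WEIGHTS))
            cnv_type = LOSS if copy_class < 2 else GAIN
        else:
            carriers = {str(rng.choice(all_samples))}
            copy_class = int(rng.choice(_EVENT_CLASSES, p=_EVENT_CLASS_WEIGHTS))
            cnv_type = LOSS if copy_class < 2 else GAIN
        events.append(
            PlantedEvent(
                interval=interval,
                label=label,
                cnv_type=cnv_type,
                copy_class=copy_class,
                carriers=frozenset(carriers),
            )
        )
    events.sort(key=lambda e: e.interval)

    boundary: dict[str, list[RawCall]] = {s: [] for s in all_samples}
    depth: dict[str, list[RawCall]] = {s: [] for s in all_samples}
    sizes = config.chrom_sizes
    for event in events:
        iv = event.interval
        for sample in sorted(event.carriers):
            boundary[sample].append(
                RawCall(sample, iv, event.cnv_type, BOUNDARY_CALLER, quality=100.0)
            )
            # jitter the depth caller's endpoints, truncated to keep overlap
            js = int(round(rng.normal(0.0, config.boundary_jitter_sd))) if config.boundary_jitter_sd else 0
            je = int(round(rng.normal(0.0, config.boundary_jitter_sd))) if config.boundary_jitter_sd else 0
            d_start = min(max(iv.start + js, 0), iv.end - 1)
            d_end = max(min(iv.end + je, sizes[iv.chrom]), d_start + 1, iv.start + 1)
            # depth noise truncated so round(2*RD) still equals the true class
            noise = float(np.clip(rng.normal(0.0, config.depth_noise_sd), -0.24, 0.24)) if config.depth_noise_sd else 0.0
            rd = max(0.0, event.copy_class / 2.0 + noise)
            depth[sample].append(
                RawCall(
                    sample,
                    GenomicInterval(iv.chrom, d_start, d_end),
                    event.cnv_type,
                    DEPTH_CALLER,
                    normalized_depth=rd,
                )
            )
    for calls in (*boundary.values(), *depth.values()):
        calls.sort(key=lambda c: c.interval)
    truth = SimulationTruth(events=events, sample_table=table, chrom_sizes=dict(sizes))
    return SimulationResult(
        config=config,
        sample_table=table,
        chrom_sizes=dict(sizes),
        boundary_calls=boundary,
        depth_calls=depth,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission (VCF + depth text + sample sheet + chrom sizes)
# ---------------------------------------------------------------------------

_VCF_TYPE = {LOSS: "DEL", GAIN: "DUP"}


def _vcf_text(calls: Sequence[RawCall], chrom_sizes: dict[str, int]) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c},length={n}>" for c, n in chrom_sizes.items()]
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end (1-based inclusive)">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for k, call in enumerate(calls, start=1):
        iv = call.interval
        svtype = _VCF_TYPE[call.cnv_type]
        lines.append(
            f"{iv.chrom}\t{iv.start + 1}\tsv{k}\tN\t<{svtype}>\t"
            f"{call.quality if call.quality is not None else '.'}\t.\t"
            f"SVTYPE={svtype};END={iv.end}"
        )
    return "\n".join(lines) + "\n"


_DEPTH_TYPE = {LOSS: "deletion", GAIN: "duplication"}


def _depth_text(calls: Sequence[RawCall]) -> str:
    lines = []
    for call in calls:
        iv = call.interval
        lines.append(
            f"{_DEPTH_TYPE[call.cnv_type]}\t{iv.chrom}:{iv.start + 1}-{iv.end}\t"
            f"{iv.length()}\t{call.normalized_depth:.6f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def write_simulation(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write per-animal VCF/depth files, the sample sheet and chrom sizes.

    Deterministic: the same result object always produces byte-identical
    files (no timestamps).
    """
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    for sample in result.sample_table.samples:
        (out / "vcf" / f"{sample}.vcf").write_text(
            _vcf_text(result.boundary_calls[sample], result.chrom_sizes)
        )
        (out / "depth" / f"{sample}.txt").write_text(_depth_text(result.depth_calls[sample]))
    write_sample_table(result.sample_table, out / "samples.tsv")
    write_chrom_sizes(result.chrom_sizes, out / "chrom.sizes")
    return {
        "vcf_dir": out / "vcf",
        "depth_dir": out / "depth",
        "sample_sheet": out / "samples.tsv",
        "chrom_sizes": out / "chrom.sizes",
    }


# ---------------------------------------------------------------------------
# annotation fixture
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTruth:
    feature_set: FeatureSet
    gff_records: dict
    genes_overlapping_events: set[str]
    genes_exon_overlapping_events: set[str]


def generate_annotation_fixture(
    config: SimulationConfig,
    truth: SimulationTruth,
    n_genes: int = 30,
) -> AnnotationTruth:
    """Place non-overlapping genes on the simulated genome and record which
    overlap planted CNV events (any feature, and exon specifically)."""
    rng = np.random.default_rng(config.seed + 104729)  # independent stream
    lengths = rng.integers(2_000, 20_000, size=n_genes)
    placed = _place_intervals(rng, config, lengths)
    kinds = rng.choice(["gene", "lnc_RNA", "pseudogene"], size=n_genes, p=[0.6, 0.2, 0.2])

    gff_records: dict = {}
    features: list[Feature] = []
    for i, (iv, kind) in enumerate(zip(placed, kinds)):
        gene_id = f"G{i + 1:04d}"
        exon_ivs: list[GenomicInterval] = []
        if kind == "gene":
            n_exons = int(rng.integers(1, 6))
            cuts = np.sort(rng.choice(np.arange(iv.start + 50, iv.end - 50), size=2 * n_exons, replace=False))
            for a, b in zip(cuts[0::2], cuts[1::2]):
                exon_ivs.append(GenomicInterval(iv.chrom, int(a), int(b) + 1))
            for e in exon_ivs:
                features.append(Feature(e, "exon", gene_id))
            from .intervals import subtract_intervals

            for intron in subtract_intervals([iv], exon_ivs):
                features.append(Feature(intron, "intron", gene_id))
        else:
            cls = "lncRNA" if kind == "lnc_RNA" else "pseudogene"
            features.append(Feature(iv, cls, gene_id))
        gff_records[gene_id] = (kind, iv, exon_ivs)

    event_union = merge_intervals(e.interval for e in truth.events)
    genes: set[str] = set()
    exon_genes: set[str] = set()
    for feat in features:
        if any(feat.interval.overlaps(iv) for iv in event_union):
            genes.add(feat.gene_id)
            if feat.feature_class == "exon":
                exon_genes.add(feat.gene_id)
    return AnnotationTruth(
        feature_set=FeatureSet(features),
        gff_records=gff_records,
        genes_overlapping_events=genes,
        genes_exon_overlapping_events=exon_genes,
    )


def write_annotation_fixture(fixture: AnnotationTruth, path: str | Path) -> None:
    write_gff3(fixture.gff_records, path)
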