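"""Readers and writers for every external format the pipeline touches.

Conversions between the external conventions (VCF and depth-caller text are
1-based inclusive; BED/bedGraph are 0-based half-open) and the internal
0-based half-open convention happen here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import pysam

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

LOSS = "loss"
GAIN = "gain"

BOUNDARY_CALLER = "boundary_caller"
DEPTH_CALLER = "depth_caller"

#: fixed ingest vocabulary mapping, applied at the I/O boundary and logged
SVTYPE_TO_CNV_TYPE = {"DEL": LOSS, "DUP": GAIN}
DEPTH_TYPE_TO_CNV_TYPE = {"deletion": LOSS, "duplication": GAIN}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class RawCall:
    """One caller's CNV call for one sample."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: Literal["loss", "gain"]
    source: Literal["boundary_caller", "depth_caller"]
    normalized_depth: float | None = None
    quality: float | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cnv_type not in (LOSS, GAIN):
            raise ValueError(f"bad cnv_type {self.cnv_type!r}")
        if self.source == DEPTH_CALLER:
            if self.normalized_depth is None or self.normalized_depth < 0:
                raise ValueError("depth_caller calls need a nonnegative normalized_depth")
        elif self.normalized_depth is not None:
            raise ValueError("normalized_depth only allowed for depth_caller calls")


@dataclass
class SampleTable:
    """Sample → breed → subspecies map with uniqueness guarantees."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        breed_sub: dict[str, str] = {}
        for sample_id, breed, subspecies in self.rows:
            if sample_id in seen:
                raise ValueError(f"duplicate sample_id {sample_id!r}")
            seen[sample_id] = breed
            if breed_sub.setdefault(breed, subspecies) != subspecies:
                raise ValueError(f"breed {breed!r} maps to more than one subspecies")
        self._breed_of = seen
        self._subspecies_of_breed = breed_sub

    @property
    def samples(self) -> list[str]:
        return [r[0] for r in self.rows]

    @property
    def breeds(self) -> list[str]:
        return sorted(self._subspecies_of_breed)

    @property
    def subspecies(self) -> list[str]:
        return sorted(set(self._subspecies_of_breed.values()))

    def breed_of(self, sample_id: str) -> str:
        return self._breed_of[sample_id]

    def subspecies_of(self, sample_id: str) -> str:
        return self._subspecies_of_breed[self._breed_of[sample_id]]

    def samples_in(self, subspecies: str) -> list[str]:
        return [s for s in self.samples if self.subspecies_of(s) == subspecies]


FEATURE_CLASSES = ("exon", "intron", "lncRNA", "pseudogene")


@dataclass(frozen=True)
class Feature:
    interval: GenomicInterval
    feature_class: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"bad feature_class {self.feature_class!r}")


@dataclass
class FeatureSet:
    features: list[Feature] = field(default_factory=list)

    def by_class(self, feature_class: str) -> list[GenomicInterval]:
        return [f.interval for f in self.features if f.feature_class == feature_class]

    def gene_ids(self) -> set[str]:
        return {f.gene_id for f in self.features}


# ---------------------------------------------------------------------------
# structural-variant VCF (boundary caller)
# ---------------------------------------------------------------------------

def read_sv_vcf(path: str | Path, sample_id: str) -> list[RawCall]:
    """Read DEL/DUP records from a structural-variant VCF as boundary-caller calls.

    POS/END are 1-based inclusive in the file; emitted intervals are 0-based
    half-open ``[POS-1, END)``. Records with other SVTYPEs are skipped and
    counted; records with END <= POS are rejected with a warning.
    """
    path = str(path)
    calls: list[RawCall] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    with vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in SVTYPE_TO_CNV_TYPE:
                skipped += 1
                continue
            end = rec.info.get("END", rec.stop)
            if end is None or end <= rec.pos:
                logger.warning("%s: record at %s:%d has END <= POS, rejected", path, rec.chrom, rec.pos)
                continue
            calls.append(
                RawCall(
                    sample_id=sample_id,
                    interval=GenomicInterval(rec.chrom, rec.pos - 1, int(end)),
                    cnv_type=SVTYPE_TO_CNV_TYPE[svtype],
                    source=BOUNDARY_CALLER,
                    quality=rec.qual,
                )
            )
    if skipped:
        logger.info("%s: skipped %d non-DEL/DUP records", path, skipped)
    return calls


# ---------------------------------------------------------------------------
# depth-caller text (CNVnator-style)
# ---------------------------------------------------------------------------

def read_depth_calls(path: str | Path, sample_id: str) -> list[RawCall]:
    """Read CNVnator-style whitespace-delimited calls.

    Line layout: ``type chrom:start-end size normalized_RD [extra ...]`` with
    1-based inclusive coordinates; emitted intervals are ``[start-1, end)``.
    A size column disagreeing with the coordinates by more than 1 bp draws a
    warning; the coordinates win. Extra columns are preserved opaquely.
    """
    path = Path(path)
    calls: list[RawCall] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
        kind, locus, size_s, rd_s = parts[:4]
        if kind not in DEPTH_TYPE_TO_CNV_TYPE:
            raise FormatError(f"{path}:{lineno}: unknown call type {kind!r}")
        try:
            chrom, _, span = locus.rpartition(":")
            lo_s, _, hi_s = span.partition("-")
            start1, end1 = int(lo_s), int(hi_s)
            size = int(float(size_s))
            depth = float(rd_s)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: cannot parse {line!r}") from exc
        if not chrom or end1 < start1:
            raise FormatError(f"{path}:{lineno}: bad locus {locus!r}")
        if abs(size - (end1 - start1 + 1)) > 1:
            logger.warning(
                "%s:%d: size %d inconsistent with %s; using coordinates", path, lineno, size, locus
            )
        calls.append(
            RawCall(
                sample_id=sample_id,
                interval=GenomicInterval(chrom, start1 - 1, end1),
                cnv_type=DEPTH_TYPE_TO_CNV_TYPE[kind],
                source=DEPTH_CALLER,
                normalized_depth=depth,
                extra=tuple(parts[4:]),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def read_gff3_features(path: str | Path) -> FeatureSet:
    """Load gene annotation into the four feature classes.

    Protein-coding genes contribute their exons plus introns computed as the
    gene span minus the exon union. ``lnc_RNA``/``lncRNA`` and ``pseudogene``
    rows contribute one interval each, keyed by their own ID. An exon that
    cannot be resolved to a parent gene is an error.
    """
    import gffutils

    from .intervals import subtract_intervals

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features: list[Feature] = []

    def _iv(f) -> GenomicInterval:
        return GenomicInterval(f.seqid, f.start - 1, f.end)

    gene_ids = set()
    for gene in db.features_of_type("gene"):
        gene_ids.add(gene.id)
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            exons.append(_iv(exon))
        for iv in exons:
            if not _iv(gene).contains(iv):
                raise FormatError(f"exon {iv.id} outside gene span of {gene.id}")
            features.append(Feature(iv, "exon", gene.id))
        for iv in subtract_intervals([_iv(gene)], exons):
            features.append(Feature(iv, "intron", gene.id))
    for kind, cls in (("lnc_RNA", "lncRNA"), ("lncRNA", "lncRNA"), ("pseudogene", "pseudogene")):
        try:
            rows = list(db.features_of_type(kind))
        except Exception:
            rows = []
        for row in rows:
            gene_ids.add(row.id)
            features.append(Feature(_iv(row), cls, row.id))
    for exon in db.features_of_type("exon"):
        parents = [p for p in db.parents(exon, featuretype="gene")]
        if not parents:
            raise FormatError(f"exon {exon.id} has no parent gene")
    return FeatureSet(features)


def write_gff3(features: Mapping[str, Sequence], path: str | Path) -> None:
    """Write a minimal GFF3 from ``{gene_id: (kind, gene_iv, [exon_ivs])}``.

    ``kind`` is one of ``gene``, ``lnc_RNA``, ``pseudogene``. Coordinates are
    converted back to 1-based inclusive.
    """
    lines = ["##gff-version 3"]
    for gene_id, (kind, gene_iv, exon_ivs) in features.items():
        lines.append(
            f"{gene_iv.chrom}\tcnvdiff\t{kind}\t{gene_iv.start + 1}\t{gene_iv.end}\t.\t+\t.\tID={gene_id}"
        )
        for k, iv in enumerate(exon_ivs, start=1):
            lines.append(
                f"{iv.chrom}\tcnvdiff\texon\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t"
                f"ID={gene_id}.exon{k};Parent={gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph / chrom.sizes
# ---------------------------------------------------------------------------

def write_bed(records: Iterable, path: str | Path) -> None:
    """Write intervals (optionally with extra columns) as BED3+.

    Each record is either a ``GenomicInterval`` or a tuple whose first element
    is one; remaining elements become additional BED columns.
    """
    lines = []
    for rec in records:
        if isinstance(rec, GenomicInterval):
            iv, attrs = rec, ()
        else:
            iv, *attrs = rec
        lines.append("\t".join([iv.chrom, str(iv.start), str(iv.end), *map(str, attrs)]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, tuple[str, ...]]]:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
        out.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])), tuple(parts[3:])))
    return out


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    """Read bedGraph coverage; overlapping intervals on one chromosome are an error."""
    rows: list[tuple[GenomicInterval, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        rows.append((GenomicInterval(parts[0], int(parts[1]), int(parts[2])), float(parts[3])))
    by_pos = sorted(rows, key=lambda r: r[0])
    for prev, cur in zip(by_pos, by_pos[1:]):
        if prev[0].chrom == cur[0].chrom and cur[0].start < prev[0].end:
            raise FormatError(f"{path}: overlapping bedGraph intervals {prev[0].id} and {cur[0].id}")
    return rows


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: chrom.sizes needs 2 columns")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def filter_to_chroms(calls: Sequence[RawCall], chroms: Iterable[str]) -> list[RawCall]:
    """Keep only calls on the listed chromosomes; log how many were dropped."""
    allowed = set(chroms)
    kept = [c for c in calls if c.interval.chrom in allowed]
    dropped = len(calls) - len(kept)
    if dropped:
        logger.info("dropped %d calls on chromosomes outside the sizes file", dropped)
    return kept


# ---------------------------------------------------------------------------
# sample sheet and genotype matrix TSV
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "breed", "subspecies"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: sample sheet must start with columns {required}")
    return SampleTable([tuple(r) for r in df[required].itertuples(index=False)])


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\tsubspecies\n")
        for sample_id, breed, subspecies in table.rows:
            fh.write(f"{sample_id}\t{breed}\t{subspecies}\n")


def write_genotype_matrix(matrix, path: str | Path) -> None:
    """Write a SegmentGenotypeMatrix as TSV (rows = segment ids, cols = samples)."""
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="segment")


def read_genotype_matrix(path: str | Path):
    from .segmentation import Segment, SegmentGenotypeMatrix

    df = pd.read_csv(path, sep="\t", index_col="segment")
    segments = [Segment(GenomicInterval.from_id(sid)) for sid in df.index]
    return SegmentGenotypeMatrix(
        segments=segments,
        samples=[str(c) for c in df.columns],
        values=df.to_numpy(dtype="int8"),
    )
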