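"""Annotation and alignment I/O with interval queries.

All internal coordinates are 0-based half-open (BED convention); GFF3/GTF
1-based inclusive coordinates are converted at the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-"})


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; message names the line number."""


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "gene"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """A collection of gene features with a per-chromosome overlap index.

    Parameters
    ----------
    features
        Gene features; ``gene_id`` must be unique across the annotation.
    chrom_sizes
        Optional chromosome lengths. When given, every feature must fit
        inside its chromosome; when omitted, sizes are inferred as the
        maximum feature end per chromosome.
    """

    def __init__(
        self,
        features: Iterable[GeneFeature],
        chrom_sizes: dict[str, int] | None = None,
    ) -> None:
        self.features: list[GeneFeature] = list(features)
        seen: set[str] = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id!r}")
            seen.add(f.gene_id)
        if chrom_sizes is None:
            chrom_sizes = {}
            for f in self.features:
                chrom_sizes[f.chrom] = max(chrom_sizes.get(f.chrom, 0), f.end)
        else:
            for f in self.features:
                size = chrom_sizes.get(f.chrom)
                if size is None:
                    raise ValueError(f"feature {f.gene_id} on unknown chrom {f.chrom}")
                if f.end > size:
                    raise ValueError(
                        f"feature {f.gene_id} ends at {f.end} beyond "
                        f"{f.chrom} length {size}"
                    )
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
        self._warned_chroms: set[str] = set()

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def get(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(gene_id)

    def query(self, chrom: str, start: int, end: int) -> list[GeneFeature]:
        """Features overlapping [start, end) on ``chrom``, sorted by
        (start, gene_id). Unknown chromosomes yield an empty list."""
        if end <= start:
            raise ValueError(f"empty query interval [{start}, {end})")
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                logger.warning("query on unknown chromosome %r", chrom)
                self._warned_chroms.add(chrom)
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.gene_id))
        return hits


def query_overlaps(
    annotation: GenomeAnnotation, chrom: str, start: int, end: int
) -> list[GeneFeature]:
    """Features of ``annotation`` overlapping the half-open [start, end)."""
    return annotation.query(chrom, start, end)


# --------------------------------------------------------------------------
# Annotation parsing


def _parse_gff_attributes(attr: str, fmt: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if fmt == "gff3":
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part or "=" not in part:
                continue
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    else:  # gtf
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if " " in part:
                k, v = part.split(" ", 1)
                out[k.strip()] = v.strip().strip('"')
    return out


_GENE_LIKE = {"gene", "pseudogene", "ncRNA_gene", "transcript", "mRNA"}


def load_annotation(path: str | Path, format: str | None = None) -> GenomeAnnotation:
    """Load a gene annotation from GFF3, GTF or BED.

    GFF3/GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is consumed as-is. Only gene-level
    records are kept from GFF3/GTF (``gene`` and close synonyms); exon and
    CDS lines are ignored.

    Parameters
    ----------
    path
        Annotation file.
    format
        One of ``gff3``, ``gtf``, ``bed``; inferred from the file suffix
        when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"gff": "gff3", "gff3": "gff3", "gtf": "gtf", "bed": "bed"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    format = format.lower()
    if format not in {"gff3", "gtf", "bed"}:
        raise ValueError(f"unsupported annotation format {format!r}")

    features: list[GeneFeature] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    feat = _parse_bed_line(fields, lineno)
                else:
                    feat = _parse_gff_line(fields, format, lineno)
            except AnnotationParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(f"line {lineno}: {exc}") from exc
            if feat is None:
                continue
            if feat.gene_id in seen_ids:
                raise AnnotationParseError(
                    f"line {lineno}: duplicate gene_id {feat.gene_id!r}"
                )
            seen_ids.add(feat.gene_id)
            features.append(feat)
    return GenomeAnnotation(features)


def _parse_bed_line(fields: list[str], lineno: int) -> GeneFeature:
    if len(fields) < 6:
        raise AnnotationParseError(f"line {lineno}: BED6 requires 6 columns")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    start, end = int(start_s), int(end_s)
    if end <= start:
        raise AnnotationParseError(f"line {lineno}: end {end} <= start {start}")
    if strand not in VALID_STRANDS:
        raise AnnotationParseError(f"line {lineno}: unknown strand {strand!r}")
    return GeneFeature(gene_id=name, chrom=chrom, start=start, end=end, strand=strand)


def _parse_gff_line(
    fields: list[str], fmt: str, lineno: int
) -> GeneFeature | None:
    if len(fields) != 9:
        raise AnnotationParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
    chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr = fields
    if ftype not in _GENE_LIKE:
        return None
    start1, end1 = int(start_s), int(end_s)
    start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
    if end <= start:
        raise AnnotationParseError(f"line {lineno}: end {end1} <= start {start1}")
    if strand not in VALID_STRANDS:
        raise AnnotationParseError(f"line {lineno}: unknown strand {strand!r}")
    attrs = _parse_gff_attributes(attr, fmt)
    gene_id = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
    if not gene_id:
        raise AnnotationParseError(f"line {lineno}: no ID/gene_id attribute")
    return GeneFeature(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand, biotype=ftype
    )


def write_bed(features: Iterable, path: str | Path, score: int = 0) -> None:
    """Write features (anything with chrom/start/end/strand and an id) as BED6."""
    with open(path, "w") as fh:
        for f in features:
            name = getattr(f, "gene_id", None) or getattr(f, "feature_id", ".")
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t{score}\t{f.strand}\n")


def write_gff3(features: Iterable, path: str | Path, source: str = "asdetect") -> None:
    """Write gene-level features as GFF3 (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            name = getattr(f, "gene_id", None) or getattr(f, "feature_id", ".")
            biotype = getattr(f, "biotype", "gene")
            fh.write(
                f"{f.chrom}\t{source}\t{biotype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={name}\n"
            )


# --------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class AlignmentRecord:
    """A single aligned read, 0-based half-open on the reference.

    ``align_strand`` is the strand the read aligned to (``-`` iff SAM FLAG
    bit 0x10 is set); the originating transcript strand is inferred
    downstream from the library protocol.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    align_strand: str
    mapq: int = 0
    is_unmapped: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if not self.is_unmapped and self.end <= self.start:
            raise ValueError(f"mapped read {self.read_id} has empty span")

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_alignment(seg: pysam.AlignedSegment) -> AlignmentRecord:
    """Convert a SAM/BAM record into an :class:`AlignmentRecord`.

    The reference span comes from the CIGAR; unmapped (0x4), secondary
    (0x100) and supplementary (0x800) flags are carried so callers can
    filter before classification.
    """
    if seg.is_unmapped:
        return AlignmentRecord(
            read_id=seg.query_name or "",
            chrom="*",
            start=0,
            end=0,
            align_strand="+",
            mapq=seg.mapping_quality,
            is_unmapped=True,
            is_secondary=seg.is_secondary,
            is_supplementary=seg.is_supplementary,
        )
    ref_len = seg.reference_length
    if ref_len is None or ref_len <= 0:
        raise ValueError(f"record {seg.query_name}: unusable CIGAR {seg.cigarstring!r}")
    return AlignmentRecord(
        read_id=seg.query_name or "",
        chrom=seg.reference_name,
        start=seg.reference_start,
        end=seg.reference_start + ref_len,
        align_strand="-" if seg.is_reverse else "+",
        mapq=seg.mapping_quality,
        is_unmapped=False,
        is_secondary=seg.is_secondary,
        is_supplementary=seg.is_supplementary,
    )


def read_sam(
    path: str | Path,
    mapq_min: int = 10,
    known_chroms: set[str] | None = None,
) -> list[AlignmentRecord]:
    """Read a SAM/BAM file and return filtered primary alignments.

    Unmapped, secondary and supplementary records and records below
    ``mapq_min`` are dropped. Records on chromosomes not in
    ``known_chroms`` (when given) are skipped with one logged warning per
    chromosome rather than raising.
    """
    records: list[AlignmentRecord] = []
    warned: set[str] = set()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for seg in fh:
            rec = parse_alignment(seg)
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapq < mapq_min:
                continue
            if known_chroms is not None and rec.chrom not in known_chroms:
                if rec.chrom not in warned:
                    logger.warning(
                        "skipping reads on unknown chromosome %r in %s", rec.chrom, path
                    )
                    warned.add(rec.chrom)
                continue
            records.append(rec)
    return records
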