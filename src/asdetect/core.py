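"""Strand inference, read classification, and reference-free assembly of
antisense transcription units.

The dUTP strand-specific protocol sequences the strand opposite the
originating transcript, so for single-end reads the transcript strand is
the reverse of the alignment strand ("reverse-stranded" libraries). Reads
whose inferred transcript strand is opposite every gene they cover are
antisense; reads covering no gene are intergenic. Antisense and intergenic
reads are pooled and merged into maximal clusters per (chromosome, strand)
— the transcription-unit models — without using the gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from asdetect.genomic_io import AlignmentRecord, GenomeAnnotation


class LibraryProtocol(str, Enum):
    """Strandedness of the sequencing library.

    ``stranded_reverse`` is the dUTP convention: the single-end read aligns
    opposite to the transcript. ``stranded_forward`` reads align on the
    transcript strand. ``unstranded`` libraries cannot support
    sense/antisense calls.
    """

    stranded_reverse = "stranded_reverse"
    stranded_forward = "stranded_forward"
    unstranded = "unstranded"


class ReadCategory(str, Enum):
    sense = "sense"
    antisense = "antisense"
    intergenic = "intergenic"
    ambiguous = "ambiguous"


@dataclass(frozen=True)
class ClassifiedRead:
    """An aligned read with its inferred transcript strand and category."""

    record: AlignmentRecord
    transcript_strand: str
    category: ReadCategory
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category is ReadCategory.intergenic and self.gene_ids:
            raise ValueError("intergenic read cannot carry gene ids")
        if self.category in (ReadCategory.sense, ReadCategory.antisense):
            if not self.gene_ids:
                raise ValueError(f"{self.category.value} read requires gene ids")


@dataclass(frozen=True)
class TranscriptModel:
    """An assembled antisense/intergenic transcription unit.

    ``feature_id`` is ``<chrom>_<start1>_<end1>`` with 1-based inclusive
    coordinates, while ``start``/``end`` stay 0-based half-open internally.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_support_reads: int
    origin: str  # antisense | intergenic | mixed

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SenseAntisensePair:
    """A link between an antisense unit and a sense gene it overlaps
    on the opposite strand."""

    feature_id: str
    gene_id: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.overlap_bp <= 0:
            raise ValueError("pair requires positive overlap")


OPPOSITE = {"+": "-", "-": "+"}


def infer_transcript_strand(record: AlignmentRecord, protocol: LibraryProtocol) -> str:
    """Transcript strand of a mapped read under the library protocol."""
    if record.is_unmapped:
        raise ValueError("cannot infer strand for an unmapped read")
    protocol = LibraryProtocol(protocol)
    if protocol is LibraryProtocol.unstranded:
        raise ValueError("unstranded protocol: transcript strand is undefined")
    if protocol is LibraryProtocol.stranded_reverse:
        return OPPOSITE[record.align_strand]
    return record.align_strand


def classify_read(
    read: AlignmentRecord,
    annotation: GenomeAnnotation,
    protocol: LibraryProtocol = LibraryProtocol.stranded_reverse,
    min_overlap_frac: float = 0.5,
) -> ClassifiedRead:
    """Classify one read as sense, antisense, intergenic or ambiguous.

    A gene qualifies when it covers at least ``min_overlap_frac`` of the
    read length. The category is sense when every qualifying gene lies on
    the read's inferred transcript strand, antisense when every qualifying
    gene lies opposite, ambiguous when qualifying genes occur on both
    strands, and intergenic when no gene qualifies.
    """
    strand = infer_transcript_strand(read, protocol)
    min_bp = min_overlap_frac * read.length
    qualifying = []
    for gene in annotation.query(read.chrom, read.start, read.end):
        overlap = min(read.end, gene.end) - max(read.start, gene.start)
        if overlap >= min_bp:
            qualifying.append(gene)
    if not qualifying:
        return ClassifiedRead(read, strand, ReadCategory.intergenic)
    strands = {g.strand for g in qualifying}
    gene_ids = tuple(g.gene_id for g in qualifying)
    if strands == {strand}:
        category = ReadCategory.sense
    elif strands == {OPPOSITE[strand]}:
        category = ReadCategory.antisense
    else:
        category = ReadCategory.ambiguous
    return ClassifiedRead(read, strand, category, gene_ids)


def classify_reads(
    reads: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    protocol: LibraryProtocol = LibraryProtocol.stranded_reverse,
    min_overlap_frac: float = 0.5,
) -> list[ClassifiedRead]:
    """Vectorised convenience wrapper over :func:`classify_read`."""
    return [
        classify_read(r, annotation, protocol, min_overlap_frac) for r in reads
    ]


def make_feature_id(chrom: str, start: int, end: int) -> str:
    """Name an interval ``<chrom>_<start1>_<end1>`` (1-based inclusive)."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    return f"{chrom}_{start + 1}_{end}"


def parse_feature_id(feature_id: str) -> tuple[str, int, int]:
    """Inverse of :func:`make_feature_id`; returns 0-based half-open."""
    chrom, start1, end1 = feature_id.rsplit("_", 2)
    return chrom, int(start1) - 1, int(end1)


def assemble_transcripts(
    reads: Sequence[ClassifiedRead],
    max_gap: int = 50,
    min_reads: int = 3,
    min_length: int = 100,
) -> list[TranscriptModel]:
    """Assemble antisense + intergenic reads into transcription units.

    Per (chromosome, transcript strand), reads sorted by start are greedily
    merged while the gap to the running cluster end is at most ``max_gap``
    bases; clusters with fewer than ``min_reads`` supporting reads or a
    span below ``min_length`` are discarded. A model is labelled
    ``antisense`` when any member read is antisense, ``intergenic`` when
    all members are intergenic. Sense and ambiguous reads are rejected.
    """
    for r in reads:
        if r.category not in (ReadCategory.antisense, ReadCategory.intergenic):
            raise ValueError(
                f"assembly accepts antisense/intergenic reads only, got {r.category.value}"
            )
    by_group: dict[tuple[str, str], list[ClassifiedRead]] = {}
    for r in reads:
        by_group.setdefault((r.record.chrom, r.transcript_strand), []).append(r)

    models: list[TranscriptModel] = []
    for (chrom, strand), group in sorted(by_group.items()):
        group.sort(key=lambda r: (r.record.start, r.record.end))
        cluster: list[ClassifiedRead] = []
        cluster_end = -1

        def flush() -> None:
            if not cluster:
                return
            start = cluster[0].record.start
            end = max(r.record.end for r in cluster)
            if len(cluster) < min_reads or end - start < min_length:
                return
            origin = (
                "antisense"
                if any(r.category is ReadCategory.antisense for r in cluster)
                else "intergenic"
            )
            models.append(
                TranscriptModel(
                    feature_id=make_feature_id(chrom, start, end),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    n_support_reads=len(cluster),
                    origin=origin,
                )
            )

        for r in group:
            if cluster and r.record.start - cluster_end > max_gap:
                flush()
                cluster = []
                cluster_end = -1
            cluster.append(r)
            cluster_end = max(cluster_end, r.record.end)
        flush()
    models.sort(key=lambda m: (m.chrom, m.start, m.end, m.strand))
    return models


def associate_antisense_with_genes(
    models: Sequence[TranscriptModel], annotation: GenomeAnnotation
) -> list[SenseAntisensePair]:
    """Pair each model with every opposite-strand gene it overlaps by >= 1 bp.

    A gene linked by at least one pair is an antisense-transcript-enriched
    (ATE) gene; one gene may pair with several models and vice versa.
    Purely intergenic models (no opposite-strand gene overlap) yield no
    pairs.
    """
    pairs: list[SenseAntisensePair] = []
    for model in models:
        for gene in annotation.query(model.chrom, model.start, model.end):
            if gene.strand == model.strand:
                continue
            overlap = min(model.end, gene.end) - max(model.start, gene.start)
            if overlap > 0:
                pairs.append(
                    SenseAntisensePair(
                        feature_id=model.feature_id,
                        gene_id=gene.gene_id,
                        overlap_bp=overlap,
                    )
                )
    pairs.sort(key=lambda p: (p.feature_id, p.gene_id))
    return pairs
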