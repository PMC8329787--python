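import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asdetect.core import (
    ClassifiedRead,
    LibraryProtocol,
    ReadCategory,
    TranscriptModel,
    assemble_transcripts,
    associate_antisense_with_genes,
    classify_read,
    infer_transcript_strand,
    make_feature_id,
    parse_feature_id,
)
from asdetect.genomic_io import AlignmentRecord, GeneFeature, GenomeAnnotation


def _read(chrom="chr1", start=0, end=75, strand="+"):
    return AlignmentRecord(
        read_id=f"r_{chrom}_{start}", chrom=chrom, start=start, end=end,
        align_strand=strand, mapq=60,
    )


def _classified(chrom, start, end, strand, category=ReadCategory.antisense):
    gene_ids = ("g",) if category is ReadCategory.antisense else ()
    return ClassifiedRead(_read(chrom, start, end, strand), strand, category, gene_ids)


# ------------------------------------------------------------ strand inference


@pytest.mark.parametrize(
    "align,protocol,expected",
    [
        ("+", LibraryProtocol.stranded_reverse, "-"),
        ("-", LibraryProtocol.stranded_reverse, "+"),
        ("+", LibraryProtocol.stranded_forward, "+"),
        ("-", LibraryProtocol.stranded_forward, "-"),
    ],
)
def test_infer_transcript_strand(align, protocol, expected):
    assert infer_transcript_strand(_read(strand=align), protocol) == expected


def test_unstranded_protocol_is_an_error():
    with pytest.raises(ValueError, match="unstranded"):
        infer_transcript_strand(_read(), LibraryProtocol.unstranded)


# ------------------------------------------------------------- classification


def test_dutp_read_inside_plus_gene_is_antisense(toy_annotation):
    # aligned "+", dUTP => transcript "-", over gA (+): antisense
    read = _read(start=1200, end=1275, strand="+")
    cr = classify_read(read, toy_annotation, LibraryProtocol.stranded_reverse)
    assert cr.category is ReadCategory.antisense
    assert cr.transcript_strand == "-"
    assert cr.gene_ids == ("gA",)


def test_dutp_read_inside_plus_gene_sense_call(toy_annotation):
    read = _read(start=1200, end=1275, strand="-")  # transcript "+"
    cr = classify_read(read, toy_annotation, LibraryProtocol.stranded_reverse)
    assert cr.category is ReadCategory.sense


def test_read_over_no_gene_is_intergenic(toy_annotation):
    cr = classify_read(_read(start=2400, end=2475), toy_annotation)
    assert cr.category is ReadCategory.intergenic
    assert cr.gene_ids == ()


def test_read_over_both_strands_is_ambiguous(toy_annotation):
    # gB (-) ends 4000, gC (+) starts 3900: [3925,4000) covers both fully-ish
    read = _read(start=3925, end=4000, strand="+")
    cr = classify_read(read, toy_annotation)
    assert cr.category is ReadCategory.ambiguous
    assert set(cr.gene_ids) == {"gB", "gC"}


def test_min_overlap_frac_gates_assignment(toy_annotation):
    # read half-in gA: overlap 37 < 0.5 * 75 -> intergenic at default
    read = _read(start=2000 - 37, end=2000 - 37 + 75, strand="+")
    assert classify_read(read, toy_annotation).category is ReadCategory.intergenic
    assert (
        classify_read(read, toy_annotation, min_overlap_frac=0.4).category
        is ReadCategory.antisense
    )


def test_strand_closure_on_toy_annotation(toy_annotation):
    """Under dUTP, reads from a "+" transcript are sense for a "+" gene and
    antisense for a "-" gene covering the same interval."""
    for gene in toy_annotation:
        for transcript_strand in "+-":
            align = "-" if transcript_strand == "+" else "+"
            read = _read(gene.chrom, gene.start, gene.start + 75, align)
            cr = classify_read(read, toy_annotation)
            assert cr.transcript_strand == transcript_strand
            if gene.gene_id in cr.gene_ids:
                expected = (
                    ReadCategory.sense
                    if gene.strand == transcript_strand
                    else ReadCategory.antisense
                )
                if cr.category is not ReadCategory.ambiguous:
                    assert cr.category is expected


def test_category_partition(toy_annotation):
    rng = np.random.default_rng(3)
    reads = [
        _read("chr1", int(s), int(s) + 75, "+" if rng.random() < 0.5 else "-")
        for s in rng.integers(0, 9900, size=300)
    ]
    cats = [classify_read(r, toy_annotation).category for r in reads]
    assert len(cats) == 300  # exactly one category per read
    from collections import Counter

    assert sum(Counter(cats).values()) == 300


# ------------------------------------------------------------------ assembly


def _coverage_union_oracle(intervals, max_gap):
    """Per-base coverage union with the gap rule, independent of the
    sweep implementation."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    covered = np.zeros(hi + 1, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    merged = []
    pos = 0
    while pos <= hi:
        if not covered[pos]:
            pos += 1
            continue
        start = pos
        end = pos
        while True:
            while end <= hi and covered[end]:
                end += 1
            # look ahead over the uncovered gap
            nxt = end
            while nxt <= hi and not covered[nxt]:
                nxt += 1
            if nxt <= hi and nxt - end <= max_gap:
                end = nxt
            else:
                break
        merged.append((start, end))
        pos = end
    return merged


def test_assemble_single_read():
    reads = [_classified("chr1", 100, 175, "-")]
    (model,) = assemble_transcripts(reads, min_reads=1, min_length=10)
    assert (model.start, model.end, model.strand) == (100, 175, "-")
    assert model.feature_id == "chr1_101_175"


def test_assemble_spec_example_gap_zero():
    reads = [
        _classified("chr1", 10, 85, "+"),
        _classified("chr1", 60, 135, "+"),
        _classified("chr1", 300, 375, "+"),
    ]
    models = assemble_transcripts(reads, max_gap=0, min_reads=1, min_length=1)
    assert [(m.start, m.end) for m in models] == [(10, 135), (300, 375)]


@pytest.mark.parametrize("max_gap", [0, 20, 50])
def test_assembly_matches_coverage_union_oracle(max_gap):
    rng = np.random.default_rng(17 + max_gap)
    starts = rng.integers(0, 3000, size=500)
    reads = [_classified("chr1", int(s), int(s) + 75, "-") for s in starts]
    models = assemble_transcripts(reads, max_gap=max_gap, min_reads=1, min_length=1)
    expected = _coverage_union_oracle([(r.record.start, r.record.end) for r in reads], max_gap)
    assert [(m.start, m.end) for m in models] == expected


def test_assembly_idempotence():
    rng = np.random.default_rng(23)
    reads = [
        _classified("chr1", int(s), int(s) + 75, "+")
        for s in rng.integers(0, 2000, size=200)
    ]
    models = assemble_transcripts(reads, min_reads=1, min_length=1)
    pseudo = [_classified(m.chrom, m.start, m.end, m.strand) for m in models]
    again = assemble_transcripts(pseudo, min_reads=1, min_length=1)
    assert [(m.start, m.end) for m in again] == [(m.start, m.end) for m in models]


def test_assembly_filters_and_origin():
    reads = [
        _classified("chr1", 0, 75, "+"),
        _classified("chr1", 10, 85, "+"),
        _classified("chr1", 20, 95, "+", ReadCategory.intergenic),
        _classified("chr1", 500, 575, "+"),  # singleton: dropped by min_reads
    ]
    models = assemble_transcripts(reads, max_gap=50, min_reads=3, min_length=90)
    assert len(models) == 1
    assert models[0].origin == "antisense"
    assert models[0].n_support_reads == 3
    only_intergenic = [
        _classified("chr1", 0, 75, "+", ReadCategory.intergenic),
        _classified("chr1", 10, 85, "+", ReadCategory.intergenic),
        _classified("chr1", 20, 95, "+", ReadCategory.intergenic),
    ]
    assert assemble_transcripts(only_intergenic, min_reads=3, min_length=90)[0].origin == "intergenic"


def test_assembly_rejects_sense_reads(toy_annotation):
    sense = ClassifiedRead(_read(), "+", ReadCategory.sense, ("gA",))
    with pytest.raises(ValueError, match="antisense/intergenic"):
        assemble_transcripts([sense])


def test_assembly_empty_input():
    assert assemble_transcripts([]) == []


# ---------------------------------------------------------------- feature ids


@pytest.mark.parametrize(
    "chrom,start,end,expected",
    [
        ("chrIII", 268286, 269650, "chrIII_268287_269650"),
        ("chrIV", 1362194, 1364695, "chrIV_1362195_1364695"),
    ],
)
def test_make_feature_id_published_naming(chrom, start, end, expected):
    assert make_feature_id(chrom, start, end) == expected


@settings(derandomize=True, max_examples=200)
@given(
    chrom=st.sampled_from(["chr1", "chrXII", "2micron_plasmid"]),
    start=st.integers(min_value=0, max_value=10**7),
    length=st.integers(min_value=1, max_value=10**5),
)
def test_feature_id_round_trip(chrom, start, length):
    fid = make_feature_id(chrom, start, start + length)
    assert parse_feature_id(fid) == (chrom, start, start + length)


# ----------------------------------------------------------------- association


def _model(chrom, start, end, strand):
    return TranscriptModel(
        feature_id=make_feature_id(chrom, start, end), chrom=chrom, start=start,
        end=end, strand=strand, n_support_reads=3, origin="antisense",
    )


def test_model_inside_gene_pairs_once(toy_annotation):
    model = _model("chr1", 1200, 1500, "-")  # inside gA (+)
    (pair,) = associate_antisense_with_genes([model], toy_annotation)
    assert (pair.gene_id, pair.overlap_bp) == ("gA", 300)


def test_two_models_one_gene_share_gene_id(toy_annotation):
    models = [_model("chr1", 1100, 1300, "-"), _model("chr1", 1500, 1900, "-")]
    pairs = associate_antisense_with_genes(models, toy_annotation)
    assert len(pairs) == 2
    assert {p.gene_id for p in pairs} == {"gA"}


def test_same_strand_model_yields_no_pair(toy_annotation):
    model = _model("chr1", 1200, 1500, "+")  # same strand as gA
    assert associate_antisense_with_genes([model], toy_annotation) == []


def test_association_matches_brute_force():
    rng = np.random.default_rng(31)
    genes = []
    pos = 0
    for i in range(40):
        pos += int(rng.integers(10, 200))
        length = int(rng.integers(50, 400))
        genes.append(
            GeneFeature(f"g{i}", "chr1", pos, pos + length, "+" if rng.random() < 0.5 else "-")
        )
        pos += length
    anno = GenomeAnnotation(genes)
    models = []
    for _ in range(60):
        s = int(rng.integers(0, pos))
        models.append(_model("chr1", s, s + int(rng.integers(20, 600)), "+" if rng.random() < 0.5 else "-"))
    got = {
        (p.feature_id, p.gene_id, p.overlap_bp)
        for p in associate_antisense_with_genes(models, anno)
    }
    expected = set()
    for m in models:
        for g in genes:
            ov = min(m.end, g.end) - max(m.start, g.start)
            if ov > 0 and g.strand != m.strand:
                expected.add((m.feature_id, g.gene_id, ov))
    assert got == expected
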