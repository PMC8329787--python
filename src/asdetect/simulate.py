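"""Synthetic stranded RNA-seq data with a known antisense truth table.

The generator emulates the study design the package targets: a compact
multi-chromosome yeast-like genome of non-overlapping stranded genes;
two conditions ("WT" and a "mut" strain in which antisense repression is
lost) with replicate libraries; negative-binomial count noise; and
dUTP-protocol single-end 75-bp reads emitted as already-aligned SAM
records (perfect alignments, CIGAR ``75M``, MAPQ 60), since alignment is
outside the package's scope. A configurable fraction of genes carries an
antisense transcription unit spiked at a fold-change in the mutant; every
gene also produces a low antisense baseline so the null background is
realistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from asdetect.core import (
    OPPOSITE,
    LibraryProtocol,
    TranscriptModel,
)
from asdetect.genomic_io import AlignmentRecord, GeneFeature, GenomeAnnotation

CONDITION_WT = "WT"
CONDITION_MUT = "mut"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Lengths are in base pairs; depths are expected reads per feature per
    replicate. ``dispersion`` is the NB dispersion phi
    (variance = mu + phi mu^2) shared by all counts. ``antisense_fold``
    multiplies the antisense baseline of spiked genes in the mutant
    condition only.
    """

    n_chroms: int = 3
    chrom_length: int = 60_000
    n_genes: int = 60
    gene_length: tuple[int, int] = (1000, 2000)
    intergenic_gap: tuple[int, int] = (200, 800)
    n_replicates: int = 3
    read_length: int = 75
    mean_sense_depth: float = 100.0
    antisense_fraction: float = 0.1
    antisense_fold: float = 4.0
    baseline_antisense: float = 8.0
    dispersion: float = 0.1
    protocol: LibraryProtocol = LibraryProtocol.stranded_reverse
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.antisense_fraction <= 1:
            raise ValueError("antisense_fraction must lie in [0, 1]")
        for name in ("n_chroms", "chrom_length", "n_replicates", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be nonnegative")
        if self.gene_length[0] < self.read_length:
            raise ValueError("genes must be at least one read long")
        self.protocol = LibraryProtocol(self.protocol)

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{r + 1}"
            for cond in (CONDITION_WT, CONDITION_MUT)
            for r in range(self.n_replicates)
        ]

    @property
    def conditions(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.sample_ids}


@dataclass
class SimulationTruth:
    """Per-gene ground truth: the spiked-antisense flag, the antisense
    interval (inside the gene body, on the opposite strand) and the
    expected per-replicate count means per condition."""

    table: pd.DataFrame  # indexed by gene_id

    @property
    def spiked_genes(self) -> list[str]:
        return list(self.table.index[self.table["spiked"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")

    @staticmethod
    def from_tsv(path: str | Path) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df["spiked"] = df["spiked"].astype(bool)
        return SimulationTruth(df)


def simulate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping stranded genes on the toy genome.

    Genes are distributed round-robin across chromosomes and laid out
    left to right with intergenic gaps drawn from the configured range;
    strands are random. Deterministic for a given seed. Raises when the
    genes cannot fit on their chromosome.
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    features: list[GeneFeature] = []
    idx = 0
    for chrom, count in zip(chroms, per_chrom):
        pos = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        for _ in range(count):
            length = int(
                rng.integers(config.gene_length[0], config.gene_length[1] + 1)
            )
            if pos + length > config.chrom_length:
                raise ValueError(
                    f"genes do not fit on {chrom} (length {config.chrom_length})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            idx += 1
            features.append(
                GeneFeature(
                    gene_id=f"g{idx:04d}",
                    chrom=chrom,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                )
            )
            pos += length + int(
                rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1)
            )
    return GenomeAnnotation(
        features, chrom_sizes={c: config.chrom_length for c in chroms}
    )


def simulate_truth(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> SimulationTruth:
    """Choose spiked genes and fix every gene's antisense interval.

    The antisense unit occupies the central 60% of the gene body (always
    more than half the gene), on the strand opposite the gene, so spiked
    units are guaranteed to associate with their gene downstream.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = list(annotation)
    n_spiked = int(round(config.antisense_fraction * len(genes)))
    spiked_idx = set(
        rng.choice(len(genes), size=n_spiked, replace=False) if n_spiked else []
    )
    rows = []
    for i, g in enumerate(genes):
        margin = g.length // 5
        as_start, as_end = g.start + margin, g.end - margin
        spiked = i in spiked_idx
        fold = config.antisense_fold if spiked else 1.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "as_start": as_start,
                "as_end": as_end,
                "as_strand": OPPOSITE[g.strand],
                "spiked": spiked,
                "fold": fold,
                "sense_mean_WT": config.mean_sense_depth,
                "sense_mean_mut": config.mean_sense_depth,
                "as_mean_WT": config.baseline_antisense,
                "as_mean_mut": config.baseline_antisense * fold,
            }
        )
    return SimulationTruth(pd.DataFrame(rows).set_index("gene_id"))


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return int(rng.poisson(lam))


def simulate_reads(
    annotation: GenomeAnnotation,
    truth: SimulationTruth,
    config: SimulationConfig,
) -> dict[str, list[AlignmentRecord]]:
    """Draw aligned single-end reads for every sample.

    Per replicate and gene, the sense read count is NB(sense mean, phi)
    and the antisense count NB(baseline x fold^[mutant & spiked], phi);
    read starts are uniform within the source interval. The alignment
    strand follows the protocol (dUTP: opposite to the transcript
    strand). Records are returned coordinate-sorted per sample and are
    byte-reproducible for a given seed.
    """
    out: dict[str, list[AlignmentRecord]] = {}
    for s_idx, sample in enumerate(config.sample_ids):
        condition = config.conditions[sample]
        rng = np.random.default_rng([config.seed, 2, s_idx])
        records: list[AlignmentRecord] = []
        serial = 0
        for gene_id, row in truth.table.iterrows():
            for kind in ("sense", "antisense"):
                if kind == "sense":
                    mean = row[f"sense_mean_{condition}"]
                    lo, hi = row["start"], row["end"]
                    strand = row["strand"]
                else:
                    mean = row[f"as_mean_{condition}"]
                    lo, hi = row["as_start"], row["as_end"]
                    strand = row["as_strand"]
                n = _nb_draw(rng, float(mean), config.dispersion)
                if n == 0:
                    continue
                max_start = max(lo, hi - config.read_length)
                starts = rng.integers(lo, max_start + 1, size=n)
                if config.protocol is LibraryProtocol.stranded_reverse:
                    align_strand = OPPOSITE[strand]
                else:
                    align_strand = strand
                for start in starts:
                    serial += 1
                    records.append(
                        AlignmentRecord(
                            read_id=f"{sample}:{gene_id}:{kind}:{serial}",
                            chrom=row["chrom"],
                            start=int(start),
                            end=int(start) + config.read_length,
                            align_strand=align_strand,
                            mapq=60,
                        )
                    )
        records.sort(key=lambda r: (r.chrom, r.start, r.read_id))
        out[sample] = records
    return out


def write_sam(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    read_length: int = 75,
) -> None:
    """Write simulated records as a headered, coordinate-sorted SAM file."""
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    ordered = sorted(records, key=lambda r: (tid[r.chrom], r.start, r.read_id))
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for r in ordered:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.align_strand == "-" else 0
            seg.reference_id = tid[r.chrom]
            seg.reference_start = r.start
            seg.mapping_quality = r.mapq
            seg.cigarstring = f"{r.end - r.start}M"
            seg.query_sequence = "N" * (r.end - r.start)
            seg.query_qualities = pysam.qualitystring_to_array("I" * (r.end - r.start))
            fh.write(seg)


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, object]:
    """Generate and write a complete fixture: annotation (GFF3 + BED),
    one SAM per sample, and the truth table. Returns the in-memory
    objects plus the file paths."""
    from asdetect.genomic_io import write_bed, write_gff3

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_genome(config)
    truth = simulate_truth(annotation, config)
    reads = simulate_reads(annotation, truth, config)

    gff = out_dir / "genes.gff3"
    bed = out_dir / "genes.bed"
    write_gff3(annotation, gff)
    write_bed(annotation, bed)
    truth_path = out_dir / "truth.tsv"
    truth.to_tsv(truth_path)
    sam_paths: dict[str, Path] = {}
    for sample, records in reads.items():
        p = out_dir / f"{sample}.sam"
        write_sam(records, p, annotation.chrom_sizes, config.read_length)
        sam_paths[sample] = p
    return {
        "annotation": annotation,
        "truth": truth,
        "reads": reads,
        "annotation_gff3": gff,
        "annotation_bed": bed,
        "truth_path": truth_path,
        "sam_paths": sam_paths,
    }


def evaluate_calls(
    up_models: Sequence[TranscriptModel], truth: SimulationTruth
) -> tuple[float, float]:
    """Score up-called antisense models against the simulation truth.

    Sensitivity is the fraction of spiked genes whose true antisense
    interval is overlapped (same strand) by at least one up-called model.
    The false-discovery proportion is the fraction of up-called models
    overlapping no spiked interval; with no calls it is 0 by convention
    (flagged in the return path by sensitivity 0).
    """
    spiked = truth.table[truth.table["spiked"]]
    hit_genes: set[str] = set()
    false_models = 0
    for m in up_models:
        matched = False
        for gene_id, row in spiked.iterrows():
            if (
                m.chrom == row["chrom"]
                and m.strand == row["as_strand"]
                and min(m.end, row["as_end"]) > max(m.start, row["as_start"])
            ):
                hit_genes.add(gene_id)
                matched = True
        if not matched:
            false_models += 1
    sensitivity = len(hit_genes) / len(spiked) if len(spiked) else 0.0
    fdp = false_models / len(up_models) if up_models else 0.0
    return sensitivity, fdp
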