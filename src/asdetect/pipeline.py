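"""End-to-end orchestration: classify -> assemble -> count -> DE ->
associate -> cross-tabulate -> enrich, with deterministic file outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from asdetect import core, genomic_io, quant, sets
from asdetect.core import LibraryProtocol, ReadCategory
from asdetect.quant import Thresholds

logger = logging.getLogger(__name__)


@dataclass
class Sample:
    name: str
    path: Path
    condition: str


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, with every threshold explicit."""

    annotation: Path
    samples: list[Sample]
    condition_a: str  # reference (e.g. WT)
    condition_b: str  # contrast (e.g. mutant)
    out_dir: Path
    protocol: LibraryProtocol = LibraryProtocol.stranded_reverse
    thresholds: Thresholds = field(default_factory=Thresholds)
    mapq_min: int = 10
    min_overlap_frac: float = 0.5
    max_gap: int = 50
    min_reads: int = 3
    min_length: int = 100
    dispersion: float | str = "common"
    term_map: Path | None = None
    annotation_format: str | None = None

    def __post_init__(self) -> None:
        self.annotation = Path(self.annotation)
        self.out_dir = Path(self.out_dir)
        self.protocol = LibraryProtocol(self.protocol)
        for cond in (self.condition_a, self.condition_b):
            if not any(s.condition == cond for s in self.samples):
                raise ValueError(f"no sample for condition {cond!r}")
        if not self.annotation.exists():
            raise FileNotFoundError(self.annotation)
        for s in self.samples:
            s.path = Path(s.path)
            if not s.path.exists():
                raise FileNotFoundError(s.path)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _write_gtf(models: Sequence[core.TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'transcript_id "{m.feature_id}"; origin "{m.origin}"; '
                f'support_reads "{m.n_support_reads}";'
            )
            fh.write(
                f"{m.chrom}\tasdetect\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run the full analysis and write all result tables under
    ``config.out_dir``. Deterministic: identical inputs and config give
    byte-identical outputs. Any stage failure removes files written so
    far and raises :class:`PipelineError` naming the stage."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "load_annotation"
    try:
        annotation = genomic_io.load_annotation(
            config.annotation, config.annotation_format
        )

        stage = "classify_reads"
        classified: dict[str, list[core.ClassifiedRead]] = {}
        summary_rows = []
        for s in config.samples:
            records = genomic_io.read_sam(
                s.path, config.mapq_min, set(annotation.chrom_sizes)
            )
            reads = core.classify_reads(
                records, annotation, config.protocol, config.min_overlap_frac
            )
            classified[s.name] = reads
            tally = {c.value: 0 for c in ReadCategory}
            for r in reads:
                tally[r.category.value] += 1
            summary_rows.append(
                {"sample": s.name, "condition": s.condition, "total": len(reads), **tally}
            )
        summary = pd.DataFrame(summary_rows).set_index("sample")
        # conservation: categories partition the filtered reads
        cat_cols = [c.value for c in ReadCategory]
        assert (summary[cat_cols].sum(axis=1) == summary["total"]).all()

        stage = "assemble_transcripts"
        pooled = [
            r
            for reads in classified.values()
            for r in reads
            if r.category in (ReadCategory.antisense, ReadCategory.intergenic)
        ]
        models = core.assemble_transcripts(
            pooled, config.max_gap, config.min_reads, config.min_length
        )

        stage = "count_reads"
        conditions = {s.name: s.condition for s in config.samples}
        lib_sizes = {s.name: float(len(classified[s.name])) for s in config.samples}
        as_reads = {
            name: [
                r
                for r in reads
                if r.category in (ReadCategory.antisense, ReadCategory.intergenic)
            ]
            for name, reads in classified.items()
        }
        sense_reads = {
            name: [r for r in reads if r.category is ReadCategory.sense]
            for name, reads in classified.items()
        }
        as_counts = quant.count_reads(
            models, as_reads, conditions, config.min_overlap_frac, lib_sizes
        )
        sense_counts = quant.count_reads(
            list(annotation), sense_reads, conditions, config.min_overlap_frac, lib_sizes
        )

        stage = "differential_expression"
        as_de = quant.differential_expression(
            as_counts,
            config.condition_a,
            config.condition_b,
            config.thresholds,
            config.dispersion,
        )
        sense_de = quant.differential_expression(
            sense_counts,
            config.condition_a,
            config.condition_b,
            config.thresholds,
            config.dispersion,
        )

        stage = "associate"
        pairs = core.associate_antisense_with_genes(models, annotation)

        stage = "set_analysis"
        gene_sets = sets.build_sets(as_de, sense_de, pairs)
        crosstab = sets.crosstab_sense_antisense(sense_de, as_de, pairs)
        up_up = sets.crosstab_table(crosstab, sense_de, as_de, pairs, "up")
        down_up = sets.crosstab_table(crosstab, sense_de, as_de, pairs, "down")
        overlap_rows = []
        for a_name, b_name in [
            ("antisense_up_genes", "sense_up"),
            ("antisense_up_genes", "sense_down"),
            ("antisense_down_genes", "sense_down"),
            ("ate_genes", "sense_up"),
        ]:
            inter, only_a, only_b, cov = sets.set_overlap(
                gene_sets[a_name], gene_sets[b_name]
            )
            overlap_rows.append(
                {
                    "set_a": a_name,
                    "set_b": b_name,
                    "intersection": inter,
                    "a_only": only_a,
                    "b_only": only_b,
                    "coverage_of_b": cov,
                }
            )
        overlap_report = pd.DataFrame(overlap_rows)

        enrichment = None
        if config.term_map is not None:
            stage = "enrichment"
            term_map = sets.TermMap.from_tsv(
                config.term_map, [g.gene_id for g in annotation]
            )
            enrichment = sets.hypergeom_enrichment(
                gene_sets["antisense_up_genes"],
                term_map,
                config.thresholds.enrichment_q,
                filter_significant=False,
            )

        stage = "write_outputs"
        emit("antisense_models.bed", lambda p: genomic_io.write_bed(models, p))
        emit("antisense_models.gtf", lambda p: _write_gtf(models, p))
        emit("read_summary.tsv", lambda p: summary.to_csv(p, sep="\t"))
        emit("antisense_counts.tsv", lambda p: as_counts.counts.to_csv(p, sep="\t"))
        emit("sense_counts.tsv", lambda p: sense_counts.counts.to_csv(p, sep="\t"))
        emit("antisense_de.tsv", lambda p: as_de.to_csv(p, sep="\t"))
        emit("sense_de.tsv", lambda p: sense_de.to_csv(p, sep="\t"))
        emit(
            "pairs.tsv",
            lambda p: pd.DataFrame(
                [(x.feature_id, x.gene_id, x.overlap_bp) for x in pairs],
                columns=["feature_id", "gene_id", "overlap_bp"],
            ).to_csv(p, sep="\t", index=False),
        )
        emit("crosstab.tsv", lambda p: crosstab.to_frame().to_csv(p, sep="\t"))
        emit("crosstab_up_up.tsv", lambda p: up_up.to_csv(p, sep="\t", index=False))
        emit(
            "crosstab_down_up.tsv", lambda p: down_up.to_csv(p, sep="\t", index=False)
        )
        emit(
            "set_overlap.tsv", lambda p: overlap_report.to_csv(p, sep="\t", index=False)
        )
        for name, gs in gene_sets.items():
            emit(
                f"set_{name}.txt",
                lambda p, gs=gs: Path(p).write_text(
                    "".join(f"{m}\n" for m in sorted(gs.members))
                ),
            )
        if enrichment is not None:
            emit("enrichment.tsv", lambda p: enrichment.to_csv(p, sep="\t", index=False))

        def write_log(p: Path) -> None:
            t = config.thresholds
            lines = [
                f"annotation\t{config.annotation}",
                f"protocol\t{config.protocol.value}",
                f"condition_a\t{config.condition_a}",
                f"condition_b\t{config.condition_b}",
                f"mapq_min\t{config.mapq_min}",
                f"min_overlap_frac\t{config.min_overlap_frac}",
                f"max_gap\t{config.max_gap}",
                f"min_reads\t{config.min_reads}",
                f"min_length\t{config.min_length}",
                f"fc_threshold\t{t.fc_threshold}",
                f"p_threshold\t{t.p_threshold}",
                f"enrichment_q\t{t.enrichment_q}",
                f"pseudocount\t{t.pseudocount}",
                f"dispersion\t{config.dispersion}",
                f"n_models\t{len(models)}",
                f"n_pairs\t{len(pairs)}",
                f"n_ate_genes\t{len(gene_sets['ate_genes'])}",
            ]
            for s in config.samples:
                lines.append(f"sample\t{s.name}\t{s.path}\t{s.condition}")
            Path(p).write_text("".join(f"{ln}\n" for ln in lines))

        emit("run_log.tsv", write_log)
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    return {
        "annotation": annotation,
        "classified": classified,
        "read_summary": summary,
        "models": models,
        "antisense_counts": as_counts,
        "sense_counts": sense_counts,
        "antisense_de": as_de,
        "sense_de": sense_de,
        "pairs": pairs,
        "gene_sets": gene_sets,
        "crosstab": crosstab,
        "crosstab_up_up": up_up,
        "crosstab_down_up": down_up,
        "set_overlap": overlap_report,
        "enrichment": enrichment,
        "out_dir": out,
    }
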