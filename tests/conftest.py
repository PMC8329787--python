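import pytest

from asdetect.genomic_io import GeneFeature, GenomeAnnotation
from asdetect.pipeline import PipelineConfig, Sample, run_pipeline
from asdetect.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two chromosomes, genes on both strands, one overlapping pair."""
    return GenomeAnnotation(
        [
            GeneFeature("gA", "chr1", 1000, 2000, "+"),
            GeneFeature("gB", "chr1", 3000, 4000, "-"),
            GeneFeature("gC", "chr1", 3900, 5000, "+"),  # overlaps gB tail
            GeneFeature("gD", "chr2", 100, 1500, "-"),
        ],
        chrom_sizes={"chr1": 10_000, "chr2": 5_000},
    )


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """The default synthetic dataset (seed 0) written to disk once."""
    out = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(seed=0)
    bundle = simulate_dataset(config, out)
    bundle["config"] = config
    return bundle


@pytest.fixture(scope="session")
def pipeline_result(sim_bundle, tmp_path_factory):
    """Full pipeline run on the default synthetic dataset."""
    config = sim_bundle["config"]
    samples = [
        Sample(name, path, config.conditions[name])
        for name, path in sim_bundle["sam_paths"].items()
    ]
    out = tmp_path_factory.mktemp("pipeline_out")
    pc = PipelineConfig(
        annotation=sim_bundle["annotation_gff3"],
        samples=samples,
        condition_a="WT",
        condition_b="mut",
        out_dir=out,
    )
    return run_pipeline(pc)
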