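import pytest

from ffpeqc.region_gc import GenomeAnnotation, Transcript, build_mrna_regions
from ffpeqc.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down generator settings for fast unit tests."""
    return SimulationConfig(
        seed=11,
        n_transcripts=60,
        n_reads_per_sample=5000,
        n_genes=400,
        n_true_variants=40,
        n_artifact_variants=60,
    )


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Two genes on one chromosome: a spliced transcript and a single-exon one."""
    return GenomeAnnotation(
        transcripts=(
            Transcript("txA", "chr1", "+", ((100, 200), (300, 400), (500, 650)), "geneA"),
            Transcript("txB", "chr1", "-", ((1000, 1600),), "geneB"),
        )
    )


@pytest.fixture(scope="session")
def toy_regions(toy_annotation):
    return build_mrna_regions(toy_annotation)
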