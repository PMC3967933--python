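import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from fusioncall.config import PipelineConfig
from fusioncall.genome_model import Annotation, GeneModel, GenomeAssembly
from fusioncall.pipeline import simulate_study
from fusioncall.synthetic_data import make_toy_reference


@pytest.fixture(scope="session")
def toy_reference():
    """Standard toy genome + annotation with all engineered decoys."""
    return make_toy_reference(seed=0)


@pytest.fixture(scope="session")
def study():
    """One simulated error-free study (reads, truth, template)."""
    return simulate_study(PipelineConfig(seed=0))


@pytest.fixture
def mini_genome():
    """A tiny hand-built two-chromosome assembly with simple genes."""
    chr_a = "".join(
        [
            "TTTT",  # 0..4 upstream
            "ATGAAACC",  # 4..12 exon 1 of gA
            "GTGTGTGTGT",  # 12..22 intron
            "GGCCTTAA",  # 22..30 exon 2 of gA
            "ACACACAC",  # 30..38 downstream
        ]
    )
    chr_b = "".join(
        [
            "TTTTTTTT",  # 0..8
            "ACGTACGTACGTACGTACGTACGTACGTACGT",  # 8..40 exon 1 of gB
            "GGGGGCCCCCGGGGGCCCCC",  # 40..60 intron
            "ATAACCCGGGTTTACGTACGTACGTACGTA",  # 60..90 exon 2 of gB (in-frame stop early)
            "ACACAC",  # 90..96
        ]
    )
    genome = GenomeAssembly({"chrA": chr_a, "chrB": chr_b})
    g_a = GeneModel("gA", "chrA", "+", ((4, 12), (22, 30)), cds_start=0)
    g_b = GeneModel("gB", "chrB", "+", ((8, 40), (60, 90)))
    annotation = Annotation([g_a, g_b])
    return genome, annotation
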