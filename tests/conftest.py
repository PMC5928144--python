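import numpy as np
import pytest

from prc2net.gene_annotation import GeneModel
from prc2net.synthetic_data import SimulationParams, generate_genome

try:  # keep hypothesis runs reproducible
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture
def toy_genes():
    """Three genes on a 30 kb chromosome: +, -, and a promoter/intron overlap."""
    return [
        GeneModel("geneA", "chr1", "+", 8000, 12000,
                  exons=((8000, 8500), (11000, 12000))),
        GeneModel("geneB", "chr1", "-", 14000, 20000,
                  exons=((14000, 14600), (19500, 20000))),
        # promoter of geneC (+, tss=21000) overlaps geneB's gene body
        GeneModel("geneC", "chr1", "+", 21000, 24000,
                  exons=((21000, 21400), (23000, 24000))),
    ]


@pytest.fixture(scope="session")
def small_layout():
    """A small planted genome reused across tests (fast to simulate)."""
    params = SimulationParams(n_genes=80, chrom_length=2_000_000,
                              stable_domain_count=40, seed=3)
    return generate_genome(params)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-scale pipeline run at seed 7, shared by tests."""
    from prc2net.pipeline import PipelineConfig, run_pipeline
    from prc2net.synthetic_data import GroundTruth

    outdir = tmp_path_factory.mktemp("run_seed7")
    report = run_pipeline(PipelineConfig(outdir=str(outdir), seed=7))
    truth = GroundTruth.from_json(outdir / "sim" / "truth.json")
    return outdir, report, truth
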