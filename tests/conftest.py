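import pytest

from cernet.annotation import Gene, GenomeAnnotation, Transcript
from cernet.pipeline import run_pipeline
from cernet.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """Default strong-effect bundle with 20 planted triplets (seed 1)."""
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle)


@pytest.fixture(scope="session")
def small_config():
    """Reduced bundle for Monte-Carlo sweeps over many seeds."""
    return dict(n_chromosomes=1, n_genes=12, n_mirnas=8, n_circrnas=12,
                n_planted_triplets=5, n_decoy_de_per_class=0)


@pytest.fixture()
def toy_annotation():
    """One 3-exon plus-strand gene: exons [100,200), [300,400), [500,600)."""
    exons = [(100, 200), (300, 400), (500, 600)]
    tr = Transcript("g1.t1", "g1", "chr1", 100, 600, "+", exons)
    gene = Gene("g1", "chr1", 100, 600, "+", [tr])
    return GenomeAnnotation([gene], {"chr1": 10_000})
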