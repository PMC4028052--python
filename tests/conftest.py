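import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from txqc import synth

settings.register_profile(
    "suite",
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    """A compact fixture genome: 20 genes, ~70 introns, 3 fusions."""
    return synth.SynthSpec(
        seed=42, genome_length=120_000, n_genes=20,
        exons_per_gene=(1, 8), n_fusions=3,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    """Genome, models, transcripts and truth for the compact fixture."""
    genome = synth.generate_genome(small_spec)
    models, transcripts, truth = synth.generate_genes(small_spec, genome)
    return genome, models, transcripts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20140222)


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
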