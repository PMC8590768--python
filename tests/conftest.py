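import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from modscreen import fixture as fx
from modscreen.simulate import apply_patches, random_transcript, simulate_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic target-gene transcript and its chromosome."""
    return fx.build_fixture_transcript()


@pytest.fixture(scope="session")
def fixture_transcript(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def fixture_genome(fixture_bundle):
    return fixture_bundle[1]


def make_transcript_on_genome(seed: int, strand: str = "+", n_codons=None, n_exons=None):
    """A random valid transcript patched into a small random genome."""
    rng = np.random.default_rng(seed)
    genome = simulate_genome({"chrR": 20_000}, 0.36, seed)
    start = int(rng.integers(200, 5_000))
    tr, patches = random_transcript(
        rng, "chrR", start, gene_id="rnd-1", strand=strand,
        n_codons=n_codons, n_exons=n_exons,
    )
    return tr, apply_patches(genome, {"chrR": patches})
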