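import pytest
from hypothesis import HealthCheck, settings

from srnadapt.simulate import LibrarySpec, make_genome, make_library

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: A realistic commercial small RNA 3' adapter (TruSeq-style), used where a
#: fixed, human-readable truth helps debugging.
TRUSEQ_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture(scope="session")
def toy_genome() -> str:
    return make_genome(10_000, seed=42)


@pytest.fixture(scope="session")
def small_library(toy_genome):
    """5,000-read adapter-bearing library with known truth (fast fixture)."""
    spec = LibrarySpec(
        adapter=TRUSEQ_ADAPTER, n_reads=5_000, adapter_fraction=0.85, seed=7
    )
    reads, manifest = make_library(spec, toy_genome)
    return reads, manifest, spec
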