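import pytest

from mcoscreen import ScoringScheme, SynthSpec, generate


@pytest.fixture(scope="session")
def scheme():
    """BLOSUM62 with BLASTP gap defaults (open 11, extend 1)."""
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic family shared across tests (seed 42)."""
    return generate(SynthSpec(rng_seed=42, n_pos=5, n_ablate=5, n_far=5,
                              n_shuffle=5, n_bins=3))


@pytest.fixture(scope="session")
def positive_refs(small_dataset):
    return [r for r in small_dataset.refs if r.role.value == "POSITIVE"]
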