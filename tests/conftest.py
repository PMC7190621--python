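import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def diploid_pair():
    """A 20 kb haplotype pair at 1% divergence with truth."""
    from haplopipe.synthetic_data import gen_diploid_genome

    return gen_diploid_genome(20_000, 0.01, seed=11)


@pytest.fixture(scope="session")
def genome_markers(diploid_pair):
    """Parent-unique 21-mer marker sets built from the haplotype pair."""
    from haplopipe.trio_binning import build_marker_sets, count_kmers

    seqA, seqB, _ = diploid_pair
    return build_marker_sets(count_kmers([seqA]), count_kmers([seqB]), min_count=1)
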