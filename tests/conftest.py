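import pytest
from hypothesis import HealthCheck, settings

from cubkit.sequence_io import count_codons
from cubkit.synthetic import (
    generate_genome,
    make_fixture_suite,
    mutation_only_spec,
    selection_spec,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out, seed=20150)
    return out


@pytest.fixture(scope="session")
def mutation_genome():
    """500 genes under compositional pressure only (s = 0)."""
    return generate_genome(mutation_only_spec(n_genes=500, seed=11))


@pytest.fixture(scope="session")
def selection_genome():
    """800 genes, quarter of them under planted selection s = 1."""
    return generate_genome(selection_spec(n_genes=800, seed=13))


@pytest.fixture(scope="session")
def mutation_counts(mutation_genome):
    records, _ = mutation_genome
    return {r.id: count_codons(r) for r in records}


@pytest.fixture(scope="session")
def selection_counts(selection_genome):
    records, _ = selection_genome
    return {r.id: count_codons(r) for r in records}
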