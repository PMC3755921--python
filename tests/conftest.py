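import pytest

from isoprimer import fixtures, load_transcriptome
from isoprimer.fixtures import FixtureSpec


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Small deterministic 5-gene fixture shared across the suite."""
    spec = FixtureSpec(seed=11, n_genes=5)
    fx = fixtures.make_genome(spec, tmp_path_factory.mktemp("fx"))
    fixtures.make_reagents(spec, fx)
    return fx


@pytest.fixture(scope="session")
def transcriptome(fixture_set):
    return load_transcriptome(
        fixture_set.fasta_path, fixture_set.gff3_path, fixture_set.id_map_path
    )
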