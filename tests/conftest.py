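import pytest
from hypothesis import HealthCheck, settings

from gffindex import store
from gffindex.synthetic import generate_gff3

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def fresh_bundle_cache():
    """Each test sees an empty index-load cache."""
    store.clear_cache()
    yield
    store.clear_cache()


@pytest.fixture
def gff_fixture(tmp_path):
    """A mid-sized nested-model annotation with interleaved blocks."""
    return generate_gff3(tmp_path / "genome.gff3", n_genes=40, seed=11,
                         interleave_fraction=0.25)


@pytest.fixture
def indexed_gff(gff_fixture):
    """Same fixture with its index bundle written to disk."""
    bundle = store.build_index_bundle(gff_fixture.path)
    store.write_bundle(bundle)
    return gff_fixture, bundle
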