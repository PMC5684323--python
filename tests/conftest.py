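import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def cassette_fixture():
    """One cassette gene, its event and unique regions (seed 0)."""
    from spliceprobe import events, simulate

    models, truth = simulate.gen_transcriptome(
        0, {"CASSETTE": 1}, include_ese2_gene=False
    )
    catalog = events.build_catalog(models)
    (event,) = catalog
    regions = events.compute_unique_regions(event)
    return models, truth, event, regions
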