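import pytest

from exomotif import simulate

FIXTURE_DIR = "tests/data/fixture"


@pytest.fixture(scope="session")
def fixture_dataset() -> simulate.SyntheticDataset:
    """The miniature fixed-seed dataset, generated in memory."""
    return simulate.generate(simulate.FIXTURE_CONFIG)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The miniature dataset written out as the pipeline input files."""
    outdir = tmp_path_factory.mktemp("fixture")
    return simulate.regenerate_reference_fixture(outdir)
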