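import pytest
from hypothesis import settings

from lncscan.annotation_io import Exon, GenomeSequence, TranscriptModel
from lncscan.synthetic import SyntheticConfig, generate_fixture

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def toy_genome():
    return GenomeSequence({"chr1": "AAAACCCCGGGGTTTT"})


@pytest.fixture
def two_exon_plus():
    return TranscriptModel(
        "t1",
        "g1",
        "chr1",
        "+",
        [Exon("chr1", 1, 4, "+"), Exon("chr1", 9, 12, "+")],
    )


@pytest.fixture
def two_exon_minus():
    return TranscriptModel(
        "t1m",
        "g1",
        "chr1",
        "-",
        [Exon("chr1", 1, 4, "-"), Exon("chr1", 9, 12, "-")],
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A compact synthetic dataset shared by the structural and CLI tests."""
    out = tmp_path_factory.mktemp("fixture_small")
    manifest = generate_fixture(SyntheticConfig(n_pct=40, n_lnct=40, seed=3), out)
    return manifest


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default-condition dataset: 200 PCT + 200 LNCT, seed 7, enough for
    a 100/100 per-class train/test split."""
    out = tmp_path_factory.mktemp("fixture_default")
    manifest = generate_fixture(SyntheticConfig(n_pct=200, n_lnct=200, seed=7), out)
    return manifest
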