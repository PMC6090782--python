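import json

import pytest
from hypothesis import settings

from circkit import io as cio
from circkit.fixtures import FixtureSpec, make_fixture
from circkit.models import Transcript

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    make_fixture(FixtureSpec(seed=FIXTURE_SEED), d)
    return d


@pytest.fixture(scope="session")
def genome(fixture_dir):
    return cio.open_genome(fixture_dir / "genome.fa")


@pytest.fixture(scope="session")
def transcripts(fixture_dir):
    return cio.read_gtf(fixture_dir / "annotation.ucsc.gtf")


@pytest.fixture(scope="session")
def circ_db(fixture_dir):
    return cio.read_circ_table(fixture_dir / "circs.tsv", fixture_dir / "circs.fa")


@pytest.fixture(scope="session")
def ground_truth(fixture_dir):
    return json.loads((fixture_dir / "ground_truth.json").read_text())


@pytest.fixture(scope="session")
def primer_rows(fixture_dir):
    lines = (fixture_dir / "primers.tsv").read_text().splitlines()[1:]
    return {name: (fwd, rev) for name, fwd, rev in (l.split("\t") for l in lines)}


@pytest.fixture
def simple_transcript():
    """Hand-built plus-strand transcript: exons [100,200) [300,400) [500,600)."""
    return Transcript.from_exon_coords(
        "TX_SIMPLE", "GENE_SIMPLE", "chrZ", "+", [(100, 200), (300, 400), (500, 600)]
    )


@pytest.fixture
def simple_transcript_minus():
    return Transcript.from_exon_coords(
        "TX_SIMPLE_M", "GENE_SIMPLE_M", "chrZ", "-", [(100, 200), (300, 400), (500, 600)]
    )
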