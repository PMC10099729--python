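import numpy as np
import pytest
from hypothesis import settings

from spliceplex.graph import TranscriptModel, build_splice_graph

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def cassette_transcripts():
    """Three-exon gene; the middle exon is skipped by the second isoform."""
    t1 = TranscriptModel("g", "t1", "chr1", "+", ((0, 100), (200, 300), (400, 500)))
    t2 = TranscriptModel("g", "t2", "chr1", "+", ((0, 100), (400, 500)))
    return [t1, t2]


@pytest.fixture
def cassette_graph(cassette_transcripts):
    return build_splice_graph(cassette_transcripts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
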