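import numpy as np
import pytest

from isoformshift.core_model import Annotation, TranscriptModel


@pytest.fixture
def tiny_annotation() -> Annotation:
    """Two genes on chr1: a 3-exon '+' gene with two isoforms and a 2-exon
    '-' gene, placed without overlap."""
    ts = [
        TranscriptModel(
            "A.t1", "GA", "chr1", "+", ((100, 200), (300, 400), (500, 600))
        ),
        TranscriptModel(
            "A.t2", "GA", "chr1", "+", ((100, 200), (300, 400), (500, 600), (700, 800))
        ),
        TranscriptModel("B.t1", "GB", "chr1", "-", ((5000, 5200), (5500, 5700))),
    ]
    return Annotation(ts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
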