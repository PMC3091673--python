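import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from mtprime.simulate import make_transcriptome
from mtprime.transcriptome import TranscriptRecord, TranscriptomePartition


@pytest.fixture
def toy_partition() -> TranscriptomePartition:
    """Tiny hand-written partition with known motif content."""
    return TranscriptomePartition(
        mrna=[
            TranscriptRecord("g1", "AATTACGTACGT", "mRNA"),
            TranscriptRecord("g2", "CCCCCCCCCCCC", "mRNA"),
            TranscriptRecord("g3", "ACGTGGGGGGGG", "mRNA"),
        ],
        rrna=[TranscriptRecord("r1", "GGGGACGTGGGG", "rRNA")],
        trna=[TranscriptRecord("t1", "TTTTTTTT", "tRNA")],
    )


@pytest.fixture(scope="session")
def planted():
    """Strict planted transcriptome at generator defaults (shared, read-only)."""
    return make_transcriptome(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
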