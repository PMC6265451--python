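import numpy as np
import pytest
from hypothesis import settings

from polterm.annotations import Transcript, TranscriptSet
from polterm.tracks import CoverageTrack

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_track(values, chrom="chrI"):
    return CoverageTrack({chrom: np.asarray(values, dtype=float)})


@pytest.fixture
def toy_genes():
    """Three isolated same-strand genes plus a minus-strand gene."""
    ts = TranscriptSet(
        [
            Transcript("a", "chrI", "+", 0, 100, "mRNA"),
            Transcript("b", "chrI", "+", 250, 350, "mRNA"),
            Transcript("c", "chrI", "+", 600, 700, "snsnoRNA"),
            Transcript("d", "chrI", "-", 900, 1000, "mRNA"),
        ],
        {"chrI": 2000},
    )
    return ts
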