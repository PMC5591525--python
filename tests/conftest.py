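import numpy as np
import pytest

from rbpgroup.intervals import GenomicInterval, Peak, PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_peakset(intervals, rbp="RBP_A", method="piranha", replicate="rep1", counts=None):
    """Build a PeakSet from (start, end) pairs on chr1:+ for terse tests."""
    peaks = []
    for k, (s, e) in enumerate(intervals):
        c = counts[k] if counts is not None else 10
        peaks.append(Peak(GenomicInterval("chr1", s, e, "+"), c))
    return PeakSet(rbp, method, replicate, peaks)


@pytest.fixture
def block_matrix():
    """Noiseless 3-block occupancy-like matrix (rank-1 blocks): 60 sites x 12 RBPs."""
    rng = np.random.default_rng(7)
    V = np.zeros((60, 12))
    for g in range(3):
        u = rng.uniform(0.3, 1.0, 20)
        v = rng.uniform(0.3, 1.0, 4)
        V[g * 20 : (g + 1) * 20, g * 4 : (g + 1) * 4] = np.outer(u, v)
    return V
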