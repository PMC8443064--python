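import numpy as np
import pytest

from epm.intervals import GenomicInterval
from epm.simulate import SyntheticTruth
from epm.states import Segment, SegmentTrack


@pytest.fixture
def truth():
    return SyntheticTruth(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(states, chrom="chr1", width=200, gaps=None):
    """A tiling track from a list of state labels; ``gaps`` marks indices
    after which a gap is inserted."""
    gaps = set(gaps or ())
    segs, pos = [], 0
    for i, st in enumerate(states):
        segs.append(Segment(chrom, pos, pos + width, st))
        pos += width
        if i in gaps:
            pos += width
    return SegmentTrack(segs)


def random_coalesced_track(rng, n_segments, n_states, n_chroms=3, width=200):
    """Random tiling track with no two touching segments sharing a state."""
    segs = []
    per = n_segments // n_chroms
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = 0
        prev = -1
        for _ in range(per):
            st = int(rng.integers(n_states))
            while st == prev:
                st = int(rng.integers(n_states))
            w = width * int(rng.integers(1, 4))
            segs.append(Segment(chrom, pos, pos + w, st + 1))
            pos += w
            prev = st
    return SegmentTrack(segs)


def transition_oracle(track):
    """Brute-force adjacent-pair enumeration plus the contingency
    expectation; independent of the implementation's bookkeeping."""
    states = sorted({s.state for s in track.segments})
    pos = {s: i for i, s in enumerate(states)}
    k = len(states)
    observed = np.zeros((k, k), dtype=int)
    by_chrom = {}
    for seg in track.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs = sorted(segs, key=lambda s: s.start)
        for i in range(len(segs) - 1):
            observed[pos[segs[i].state], pos[segs[i + 1].state]] += 1
    n = observed.sum()
    expected = np.zeros((k, k))
    enrichment = np.full((k, k), np.nan)
    if n:
        for x in range(k):
            for y in range(k):
                expected[x, y] = observed[x, :].sum() * observed[:, y].sum() / n
                if expected[x, y] > 0:
                    enrichment[x, y] = observed[x, y] / expected[x, y]
    return states, observed, expected, enrichment, int(n)


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)
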