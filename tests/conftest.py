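import numpy as np
import pytest

from otterliq.datatypes import CopyRatioSegment, GenomicInterval, SegmentSet


def make_segment(log2, n_bins=150, contig="chr1", start=0):
    return CopyRatioSegment(
        interval=GenomicInterval(contig, start, start + n_bins * 10_000),
        log2_ratio=log2,
        n_bins=n_bins,
    )


def make_segment_set(log2s, n_bins=150, sample_id="test"):
    segs = [
        make_segment(x, n_bins=n_bins, contig=f"chr{i + 1}")
        for i, x in enumerate(log2s)
    ]
    return SegmentSet(segs, sample_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
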