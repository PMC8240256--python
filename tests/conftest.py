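import numpy as np
import pytest

from exapt.intervals import GenomeInterval, RepeatAnnotation
from exapt.simulate import default_consensus


def iv(chrom, start, end, **kwargs):
    return GenomeInterval(chrom, start, end, **kwargs)


def rep(chrom, start, end, family, class_name="SINE", **kwargs):
    return RepeatAnnotation(
        interval=GenomeInterval(chrom, start, end, **kwargs),
        family=family,
        class_name=class_name,
    )


def brute_classify(peaks, repeats, min_fraction=0.5):
    """Per-peak best-repeat attribution by exhaustive pairwise overlap."""
    out = []
    for pk in peaks:
        best = None  # (overlap, start, end, repeat)
        for r in repeats:
            ov = pk.overlap_bp(r.interval)
            if ov <= 0:
                continue
            key = (-ov, r.interval.start, r.interval.end)
            if best is None or key < best[0]:
                best = (key, ov, r)
        if best is not None and best[1] >= min_fraction * pk.length:
            out.append(("RABS", best[1], best[2]))
        else:
            out.append(("Non-RABS", best[1] if best else 0, None))
    return out


def brute_nearest(query, subjects):
    """Exhaustive nearest-subject scan; ties resolved to leftmost start."""
    best = None
    for s in subjects:
        if s.chrom != query.chrom:
            continue
        gap = max(0, max(s.start - query.end, query.start - s.end))
        key = (gap, s.start, s.end)
        if best is None or key < best[0]:
            best = (key, s, gap)
    if best is None:
        return None, None
    return best[1], best[2]


@pytest.fixture
def consensus_model():
    return default_consensus()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
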