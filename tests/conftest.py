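import pytest
from hypothesis import settings

from eccnano import CallerParams, build_consensus
from eccnano.alignment import AlignmentSegment, ReadChain

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy():
    """5 kb consensus with 400 bp LTRs (T=5000, L=400)."""
    return build_consensus("toy", internal_length=4200, ltr_length=400, gc=0.45, seed=1)


@pytest.fixture(scope="session")
def mini():
    """Miniature consensus for exhaustive-grid checks (T=50, L=10)."""
    return build_consensus("mini", internal_length=30, ltr_length=10, gc=0.5, seed=2)


@pytest.fixture(scope="session")
def params():
    return CallerParams()


def seg(
    ts,
    te,
    rs=None,
    re=None,
    read_id="q",
    target="toy",
    strand="+",
    target_length=5000,
    mapq=60,
    read_length=0,
):
    """Shorthand segment builder; read coords default to target span at 0."""
    if rs is None:
        rs, re = 0, te - ts
    return AlignmentSegment(
        read_id=read_id,
        read_start=rs,
        read_end=re,
        target=target,
        target_start=ts,
        target_end=te,
        strand=strand,
        mapq=mapq,
        read_length=read_length,
        target_length=target_length,
    )


def chain_of(*segments, read_id="q", target="toy"):
    return ReadChain(read_id=read_id, target=target, segments=tuple(segments))


def two_segment_chain(ts1, te1, ts2, te2, read_gap=0, strand="+", target="toy", target_length=5000):
    """Chain of two segments laid consecutively on the read with the given gap."""
    len1, len2 = te1 - ts1, te2 - ts2
    a = seg(ts1, te1, 0, len1, strand=strand, target=target, target_length=target_length)
    b = seg(
        ts2, te2, len1 + read_gap, len1 + read_gap + len2,
        strand=strand, target=target, target_length=target_length,
    )
    return chain_of(a, b, target=target)
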