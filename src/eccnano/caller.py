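"""Circularity calling and mechanistic circle typing.

A rolling-circle-amplified read of a circular molecule aligns to the linear
consensus as a chain of segments that wrap around the template. Two rules
drive the caller:

**Circularity.** A read is circular DNA when it has at least two alignments
to the transposon and every consecutive pair is directly adjacent on the
read, within ``adjacency_tol`` (default 100 bp) of each other, or
overlapping. Adjacency is measured in read coordinates, which remains valid
for rearranged circles whose target coordinates jump at the join.

**Junction deficit.** Across one wrap junction, with consensus length T,
the number of consensus bases unaccounted for is

    M = (T - upstream.target_end) + downstream.target_start - read_gap

where ``read_gap`` = downstream.read_start - upstream.read_end (negative
when the two alignments overlap on the read). Because the two LTRs are
identical, an aligner may assign the shared LTR bases of a junction to the
upstream tail, the downstream head, or both; M is invariant to that choice.
M ≈ L (the LTR length) identifies a 1-LTR junction — the two end-mapping
portions of the read "overlap by the length of the LTR" — and M ≈ 0 a
2-LTR junction with zero overlap between the mapped regions.

Full-length calls additionally require the read to map across the whole
internal interval; reads covering exactly one LTR are 1-LTR rearranged,
reads covering neither are 0-LTR rearranged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import AlignmentSegment, ReadChain, chain_segments
from .consensus import CircleType, TransposonConsensus
from .errors import ConfigurationError, ParameterError, ReferenceError_

__all__ = [
    "CallerParams",
    "JunctionStat",
    "CircleCall",
    "is_circular",
    "junction_deficit",
    "covered_union",
    "classify_circle",
    "call_circles",
    "calls_to_frame",
    "summarize_calls",
]


@dataclass(frozen=True)
class CallerParams:
    """Tolerances of the circle caller.

    adjacency_tol: maximum read-coordinate gap (bp) between consecutive
        alignments of a circular read; overlaps always pass.
    cover_tol: slack (bp) allowed at each end when deciding that a read
        fully maps across the internal interval.
    ltr_tol: slack (bp) on the junction deficit M when matching it to the
        LTR length (1-LTR) or to zero (2-LTR), and on LTR coverage.
    """

    adjacency_tol: int = 100
    cover_tol: int = 100
    ltr_tol: int = 50

    def __post_init__(self) -> None:
        if min(self.adjacency_tol, self.cover_tol, self.ltr_tol) < 0:
            raise ParameterError("caller tolerances must be non-negative")


@dataclass(frozen=True)
class JunctionStat:
    """Geometry of one junction between consecutive segments of a chain."""

    upstream: AlignmentSegment
    downstream: AlignmentSegment
    read_gap: int
    deficit: int | None  # None for cross-strand junctions
    cross_strand: bool
    internal_join: bool


@dataclass(frozen=True)
class CircleCall:
    """Per-read verdict: circularity, structural type, junction evidence."""

    read_id: str
    family: str
    circle_type: CircleType
    junctions: tuple[JunctionStat, ...]
    covered: tuple[tuple[int, int], ...]
    n_monomers: float


def is_circular(chain: ReadChain, params: CallerParams) -> bool:
    """True iff the chain has ≥2 segments and every consecutive pair is
    adjacent on the read within ``adjacency_tol`` (or overlapping)."""
    segs = chain.segments
    if len(segs) < 2:
        return False
    return all(
        b.read_start - a.read_end <= params.adjacency_tol for a, b in zip(segs, segs[1:])
    )


def junction_deficit(
    upstream: AlignmentSegment,
    downstream: AlignmentSegment,
    consensus: TransposonConsensus,
) -> int:
    """Consensus bases unaccounted for across a wrap junction (M).

    Both segments must lie on the same strand; ``upstream`` precedes
    ``downstream`` on the read. On the minus strand the read traverses the
    consensus backwards, so the roles of the two target ends swap.
    """
    if upstream.strand != downstream.strand:
        raise ParameterError("cross-strand junction has no deficit; flag it instead")
    T = consensus.length
    gap = downstream.read_start - upstream.read_end
    if upstream.strand == "+":
        return (T - upstream.target_end) + downstream.target_start - gap
    return (T - downstream.target_end) + upstream.target_start - gap


def _junction_stat(
    upstream: AlignmentSegment,
    downstream: AlignmentSegment,
    consensus: TransposonConsensus,
    params: CallerParams,
) -> JunctionStat:
    gap = downstream.read_start - upstream.read_end
    cross = upstream.strand != downstream.strand
    deficit = None if cross else junction_deficit(upstream, downstream, consensus)
    # where does the read re-enter the consensus after the junction? On the
    # minus strand the downstream segment is traversed high-to-low, so the
    # entry point is its high end.
    if cross:
        internal = False
    else:
        entry = downstream.target_start if upstream.strand == "+" else downstream.target_end
        L, T = consensus.ltr_length, consensus.length
        internal = L + params.ltr_tol < entry < T - L - params.ltr_tol
    return JunctionStat(
        upstream=upstream,
        downstream=downstream,
        read_gap=gap,
        deficit=deficit,
        cross_strand=cross,
        internal_join=internal,
    )


def covered_union(chain: ReadChain) -> tuple[tuple[int, int], ...]:
    """Sorted, merged union of the chain's target intervals."""
    ivs = sorted((s.target_start, s.target_end) for s in chain.segments)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _covers(union: Sequence[tuple[int, int]], start: int, end: int, tol: int) -> bool:
    """Does some single merged interval span [start, end) to within tol?"""
    return any(a <= start + tol and b >= end - tol for a, b in union)


def classify_circle(
    chain: ReadChain, consensus: TransposonConsensus, params: CallerParams
) -> CircleCall:
    """Assign one structural circle type to a read chain.

    Decision order: (1) chains failing the circularity rule are
    NOT_CIRCULAR. (2) Chains mapping across the whole internal interval
    whose junction deficits vote (by strict majority) M ≈ L are 1-LTR
    full-length; M ≈ 0, 2-LTR full-length. (3) Otherwise a chain fully
    covering exactly one LTR is 1-LTR rearranged, (4) one covering neither
    LTR is 0-LTR rearranged, and (5) the remainder — both LTRs covered but
    inconsistent or intermediate junctions — is AMBIGUOUS. Cross-strand
    junctions carry no deficit and so can never vote for a full-length
    type.
    """
    if consensus.ltr_length <= 0:
        raise ConfigurationError(f"{consensus.name}: consensus lacks an LTR annotation")
    T, L = consensus.length, consensus.ltr_length
    segs = chain.segments
    junctions = tuple(
        _junction_stat(a, b, consensus, params) for a, b in zip(segs, segs[1:])
    )
    union = covered_union(chain)
    circle_span = sum(e - s for s, e in union)
    n_monomers = (
        sum(s.target_span for s in segs) / circle_span if circle_span else 0.0
    )

    def call(circle_type: CircleType) -> CircleCall:
        return CircleCall(
            read_id=chain.read_id,
            family=chain.target,
            circle_type=circle_type,
            junctions=junctions,
            covered=union,
            n_monomers=n_monomers,
        )

    if not is_circular(chain, params):
        return call(CircleType.NOT_CIRCULAR)

    n_one = n_two = n_other = 0
    for j in junctions:
        if j.deficit is not None and abs(j.deficit - L) <= params.ltr_tol:
            n_one += 1
        elif j.deficit is not None and abs(j.deficit) <= params.ltr_tol:
            n_two += 1
        else:
            n_other += 1

    full_internal = _covers(union, L, T - L, params.cover_tol)
    ltr5 = _covers(union, 0, L, params.ltr_tol)
    ltr3 = _covers(union, T - L, T, params.ltr_tol)

    if full_internal and n_one > max(n_two, n_other):
        return call(CircleType.ONE_LTR_FULL)
    if full_internal and n_two > max(n_one, n_other):
        return call(CircleType.TWO_LTR_FULL)
    if ltr5 != ltr3:
        return call(CircleType.ONE_LTR_REARRANGED)
    if not ltr5 and not ltr3:
        return call(CircleType.ZERO_LTR_REARRANGED)
    return call(CircleType.AMBIGUOUS)


def call_circles(
    segments: Iterable[AlignmentSegment],
    consensus_set: Mapping[str, TransposonConsensus],
    params: CallerParams | None = None,
    extra_targets: frozenset[str] | set[str] = frozenset(),
) -> list[CircleCall]:
    """Classify every read with at least one transposon alignment.

    Reads are first reduced to their dominant target (largest summed
    aligned bases); chains on targets in ``extra_targets`` (e.g. the
    mitochondrial control) are skipped silently, while an alignment to any
    other unknown target raises. Output is sorted by family then read id.
    """
    params = params or CallerParams()
    calls = []
    for chain in chain_segments(segments, dominant_only=True):
        if chain.target in extra_targets:
            continue
        if chain.target not in consensus_set:
            raise ReferenceError_(
                f"alignment target {chain.target!r} is not in the consensus set"
            )
        calls.append(classify_circle(chain, consensus_set[chain.target], params))
    calls.sort(key=lambda c: (c.family, c.read_id))
    return calls


def calls_to_frame(calls: Sequence[CircleCall]) -> pd.DataFrame:
    """Flatten calls to a TSV-writable table."""
    return pd.DataFrame(
        [
            dict(
                read_id=c.read_id,
                family=c.family,
                circle_type=c.circle_type.value,
                n_junctions=len(c.junctions),
                n_monomers=round(c.n_monomers, 3),
                covered=",".join(f"{s}-{e}" for s, e in c.covered),
            )
            for c in calls
        ],
        columns=["read_id", "family", "circle_type", "n_junctions", "n_monomers", "covered"],
    )


#: the four mechanistic classes reported as published-style proportions;
#: AMBIGUOUS reads are tallied separately and excluded from proportions
PROPORTION_TYPES = (
    CircleType.ONE_LTR_FULL,
    CircleType.TWO_LTR_FULL,
    CircleType.ONE_LTR_REARRANGED,
    CircleType.ZERO_LTR_REARRANGED,
)


def summarize_calls(calls: Sequence[CircleCall]) -> dict:
    """Per-family counts per type plus circle-type proportions (%)."""
    summary: dict = {}
    by_family: dict[str, list[CircleCall]] = {}
    for c in calls:
        by_family.setdefault(c.family, []).append(c)
    for family, fam_calls in sorted(by_family.items()):
        counts = {t.value: 0 for t in CircleType if t != CircleType.MITO}
        for c in fam_calls:
            counts[c.circle_type.value] += 1
        typed = sum(counts[t.value] for t in PROPORTION_TYPES)
        proportions = {
            t.value: (100.0 * counts[t.value] / typed if typed else 0.0)
            for t in PROPORTION_TYPES
        }
        summary[family] = dict(
            n_reads=len(fam_calls),
            n_circular=sum(
                1
                for c in fam_calls
                if c.circle_type not in (CircleType.NOT_CIRCULAR, CircleType.AMBIGUOUS)
            ),
            counts=counts,
            type_percent=proportions,
        )
    return summary
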