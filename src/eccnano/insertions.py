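"""One-end-read scan for transposon copies in genomic DNA.

A *one-end read* carries at least ``end_min`` (default 1 kb) of a
transposon terminus plus at least ``flank_min`` (default 200 bp) of
flanking sequence. The flank decides the read's fate:

* flank aligned to the same transposon family — kept as a potential
  circular-DNA read and typed by junction geometry (1-LTR full-length,
  2-LTR full-length, or 1-LTR rearranged / nested copy);
* flank with at least ``flank_min`` bases of unique (non-repeat) genomic
  sequence — retained and its junction site used to locate the copy;
* flank entirely inside annotated repeats — discarded, since the read
  cannot be assigned a genomic location.

Unique-flank reads are clustered per family and chromosome by single
linkage: junction sites within ``cluster_window`` (default 2 kb) of each
other belong to the same candidate copy.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .alignment import AlignmentSegment
from .caller import junction_deficit
from .consensus import TransposonConsensus
from .errors import ParameterError

__all__ = [
    "ScanParams",
    "FlankClass",
    "Fig5dType",
    "OneEndRead",
    "CandidateCopy",
    "find_one_end_reads",
    "intersect_repeats",
    "classify_flank",
    "type_te_flanked_reads",
    "cluster_copies",
    "scan_insertions",
    "one_end_reads_to_frame",
    "copies_to_frame",
]


@dataclass(frozen=True)
class ScanParams:
    """Thresholds of the one-end-read scan.

    end_min: minimum transposon bases reaching a consensus terminus (bp).
    flank_min: minimum flanking bases aligned beyond the junction, and the
        minimum unique (non-repeat) bases for a flank to count as unique.
    cluster_window: single-linkage distance for grouping junction sites
        into one candidate copy (sites exactly at the window merge).
    ltr_tol: slack on terminus matching and junction-deficit comparisons.
    gap_tol: maximum read-coordinate gap between the transposon segment
        and its flank segment.
    """

    end_min: int = 1000
    flank_min: int = 200
    cluster_window: int = 2000
    ltr_tol: int = 50
    gap_tol: int = 100

    def __post_init__(self) -> None:
        if min(self.end_min, self.flank_min, self.cluster_window) <= 0:
            raise ParameterError("scan thresholds must be positive")


class FlankClass(str, enum.Enum):
    UNIQUE = "unique"
    SAME_TE = "same_te"
    REPEAT_DISCARD = "repeat_discard"


class Fig5dType(str, enum.Enum):
    """Structural types of transposon-flanked one-end reads."""

    ONE_LTR_FC = "one_ltr_full_circle"
    TWO_LTR_FC = "two_ltr_full_circle"
    ONE_LTR_REARRANGED_OR_NESTED = "one_ltr_rearranged_or_nested"


@dataclass(frozen=True)
class OneEndRead:
    """A read spanning a transposon terminus into flanking sequence."""

    read_id: str
    family: str
    te_end: str  # "5p" or "3p"
    te_aligned: int
    flank_target: str
    flank_interval: tuple[int, int]
    flank_class: FlankClass | None = None
    genomic_site: int | None = None
    fig5d_type: Fig5dType | None = None
    # junction evidence, ordered along the read (used for typing)
    upstream: AlignmentSegment | None = None
    downstream: AlignmentSegment | None = None


@dataclass(frozen=True)
class CandidateCopy:
    """A cluster of unique-flank junction sites marking one copy."""

    family: str
    chromosome: str
    site_window: tuple[int, int]
    supporting_reads: tuple[str, ...]
    ends_seen: frozenset[str]


def _flank_candidates(
    segs: Sequence[AlignmentSegment], j: int, side: str, params: ScanParams
) -> list[tuple[int, AlignmentSegment]]:
    """Segments providing ≥ flank_min aligned bases beyond read position j."""
    out = []
    for seg in segs:
        if side == "right":
            extent = seg.read_end - max(j, seg.read_start)
            near = seg.read_start <= j + params.gap_tol
        else:
            extent = min(j, seg.read_end) - seg.read_start
            near = seg.read_end >= j - params.gap_tol
        if near and extent >= params.flank_min:
            out.append((extent, seg))
    out.sort(key=lambda x: (-x[0], x[1].read_start))
    return out


def _genomic_flank(
    seg: AlignmentSegment, j: int, side: str
) -> tuple[int, tuple[int, int]]:
    """Junction site and flank interval in target coordinates.

    The site is the target-forward-strand coordinate of the flank base
    adjacent to the transposon terminus (read position j)."""
    if seg.strand == "+":
        site = seg.target_start + (j - seg.read_start)
    else:
        site = seg.target_end - (j - seg.read_start)
    site = min(max(site, seg.target_start), seg.target_end)
    right_of_site = (side == "right") == (seg.strand == "+")
    flank = (site, seg.target_end) if right_of_site else (seg.target_start, site)
    return site, flank


def find_one_end_reads(
    segments: Iterable[AlignmentSegment],
    consensus_set: Mapping[str, TransposonConsensus],
    params: ScanParams | None = None,
) -> list[OneEndRead]:
    """Find reads with ≥ end_min transposon bases reaching a consensus
    terminus, immediately followed on the read by ≥ flank_min bases aligned
    elsewhere. One record is emitted per qualifying junction.

    Flank priority: a same-family consensus flank wins (potential circle),
    then a genomic flank (class decided later against the repeat
    annotation), then a different-family consensus flank (unplaceable,
    discarded as repeat).
    """
    params = params or ScanParams()
    by_read: dict[str, list[AlignmentSegment]] = {}
    for seg in segments:
        by_read.setdefault(seg.read_id, []).append(seg)

    out: list[OneEndRead] = []
    for read_id in sorted(by_read):
        segs = sorted(by_read[read_id], key=lambda s: (s.read_start, s.read_end))
        te_segs = [s for s in segs if s.target in consensus_set]
        for te_seg in te_segs:
            cons = consensus_set[te_seg.target]
            if te_seg.target_span < params.end_min:
                continue
            termini = []
            if te_seg.target_end >= cons.length - params.ltr_tol:
                termini.append("3p")
            if te_seg.target_start <= params.ltr_tol:
                termini.append("5p")
            for te_end in termini:
                # read side of the flank: a 3' terminus sits at the read end
                # of a forward segment, at the read start of a reverse one
                side = "right" if (te_end == "3p") == (te_seg.strand == "+") else "left"
                j = te_seg.read_end if side == "right" else te_seg.read_start
                others = [s for s in segs if s is not te_seg]
                candidates = _flank_candidates(others, j, side, params)
                same_te = [s for _, s in candidates if s.target == te_seg.target]
                genomic = [s for _, s in candidates if s.target not in consensus_set]
                other_te = [
                    s
                    for _, s in candidates
                    if s.target in consensus_set and s.target != te_seg.target
                ]
                if same_te:
                    flank_seg = same_te[0]
                    upstream, downstream = (
                        (te_seg, flank_seg) if side == "right" else (flank_seg, te_seg)
                    )
                    out.append(
                        OneEndRead(
                            read_id=read_id,
                            family=te_seg.target,
                            te_end=te_end,
                            te_aligned=te_seg.target_span,
                            flank_target=flank_seg.target,
                            flank_interval=(flank_seg.target_start, flank_seg.target_end),
                            flank_class=FlankClass.SAME_TE,
                            upstream=upstream,
                            downstream=downstream,
                        )
                    )
                elif genomic:
                    flank_seg = genomic[0]
                    site, flank = _genomic_flank(flank_seg, j, side)
                    out.append(
                        OneEndRead(
                            read_id=read_id,
                            family=te_seg.target,
                            te_end=te_end,
                            te_aligned=te_seg.target_span,
                            flank_target=flank_seg.target,
                            flank_interval=flank,
                            genomic_site=site,
                            upstream=te_seg if side == "right" else flank_seg,
                            downstream=flank_seg if side == "right" else te_seg,
                        )
                    )
                elif other_te:
                    flank_seg = other_te[0]
                    out.append(
                        OneEndRead(
                            read_id=read_id,
                            family=te_seg.target,
                            te_end=te_end,
                            te_aligned=te_seg.target_span,
                            flank_target=flank_seg.target,
                            flank_interval=(flank_seg.target_start, flank_seg.target_end),
                            flank_class=FlankClass.REPEAT_DISCARD,
                        )
                    )
    return out


WAO_COLUMNS = [
    "chrom", "start", "end", "name",
    "r_chrom", "r_start", "r_end", "r_name", "overlap",
]


def intersect_repeats(
    intervals: pd.DataFrame | Sequence[tuple], repeat_bed: pd.DataFrame
) -> pd.DataFrame:
    """Write-all-overlap intersection of query intervals with a repeat BED.

    Each query yields one row per overlapping repeat with the overlap
    length in bp; a query with no overlap yields exactly one row with a
    null feature (".", -1 coordinates) and overlap 0.
    """
    if not isinstance(intervals, pd.DataFrame):
        intervals = pd.DataFrame(
            list(intervals), columns=["chrom", "start", "end", "name"][: len(intervals[0])]
        )
        if "name" not in intervals:
            intervals["name"] = "."
    trees: dict[str, IntervalTree] = {}
    for row in repeat_bed.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    rows = []
    for q in intervals.itertuples(index=False):
        hits = sorted(
            trees.get(q.chrom, IntervalTree()).overlap(q.start, q.end),
            key=lambda iv: (iv.begin, iv.end, iv.data),
        )
        if not hits:
            rows.append((q.chrom, q.start, q.end, q.name, ".", -1, -1, ".", 0))
        for iv in hits:
            overlap = min(q.end, iv.end) - max(q.start, iv.begin)
            rows.append(
                (q.chrom, q.start, q.end, q.name, q.chrom, iv.begin, iv.end, iv.data, overlap)
            )
    return pd.DataFrame(rows, columns=WAO_COLUMNS)


def _unique_bases(flank: tuple[int, int], repeats: Sequence[tuple[int, int]]) -> int:
    """Flank bases outside the union of the given repeat intervals."""
    start, end = flank
    clipped = sorted(
        (max(start, s), min(end, e)) for s, e in repeats if max(start, s) < min(end, e)
    )
    covered = 0
    cursor = start
    for s, e in clipped:
        if e > cursor:
            covered += e - max(s, cursor)
            cursor = max(cursor, e)
    return (end - start) - covered


def classify_flank(
    one_end_read: OneEndRead,
    repeat_overlaps: pd.DataFrame,
    consensus_set: Mapping[str, TransposonConsensus],
    params: ScanParams | None = None,
) -> FlankClass:
    """Decide the flank class of one read.

    Same-transposon flanks were fixed at discovery time; a genomic flank is
    UNIQUE when at least ``flank_min`` of its bases fall outside every
    annotated repeat, and REPEAT_DISCARD otherwise. ``repeat_overlaps`` is
    the write-all-overlap table for this read's flank interval.
    """
    params = params or ScanParams()
    if one_end_read.flank_class is not None:
        return one_end_read.flank_class
    if one_end_read.flank_target in consensus_set:
        return FlankClass.REPEAT_DISCARD
    hits = repeat_overlaps[repeat_overlaps["r_start"] >= 0]
    repeats = [(int(r.r_start), int(r.r_end)) for r in hits.itertuples(index=False)]
    unique = _unique_bases(one_end_read.flank_interval, repeats)
    return FlankClass.UNIQUE if unique >= params.flank_min else FlankClass.REPEAT_DISCARD


def type_te_flanked_reads(
    one_end_reads: Sequence[OneEndRead],
    consensus: TransposonConsensus,
    params: ScanParams | None = None,
) -> list[OneEndRead]:
    """Assign a structural type to every same-transposon-flanked read.

    The junction deficit M across the terminus junction discriminates the
    classes: M ≈ LTR length means the two end-mapping portions share the
    LTR (a 1-LTR full-length circle read); M ≈ 0 with both termini mapped
    means direct end-to-end joining (2-LTR circle read); a flank joining
    into internal sequence — and any other geometry, including
    cross-strand joins — is a 1-LTR rearranged circle or a nested genomic
    copy, indistinguishable from one-end evidence alone.
    """
    params = params or ScanParams()
    T, L = consensus.length, consensus.ltr_length
    typed = []
    for oer in one_end_reads:
        if oer.flank_class != FlankClass.SAME_TE:
            typed.append(oer)
            continue
        up, down = oer.upstream, oer.downstream
        fig5d = Fig5dType.ONE_LTR_REARRANGED_OR_NESTED
        if up is not None and down is not None and up.strand == down.strand:
            m = junction_deficit(up, down, consensus)
            if up.strand == "+":
                exits_end = up.target_end >= T - params.ltr_tol
                enters_start = down.target_start <= params.ltr_tol
            else:
                exits_end = down.target_end >= T - params.ltr_tol
                enters_start = up.target_start <= params.ltr_tol
            if abs(m - L) <= params.ltr_tol:
                fig5d = Fig5dType.ONE_LTR_FC
            elif abs(m) <= params.ltr_tol and exits_end and enters_start:
                fig5d = Fig5dType.TWO_LTR_FC
        typed.append(replace(oer, fig5d_type=fig5d))
    return typed


def cluster_copies(
    one_end_reads: Sequence[OneEndRead], params: ScanParams | None = None
) -> list[CandidateCopy]:
    """Single-linkage clustering of unique-flank junction sites.

    Sites within ``cluster_window`` of each other (inclusive) on the same
    chromosome and family belong to one candidate copy; the clustering is
    order-invariant and idempotent.
    """
    params = params or ScanParams()
    groups: dict[tuple[str, str], list[OneEndRead]] = {}
    for oer in one_end_reads:
        if oer.flank_class != FlankClass.UNIQUE or oer.genomic_site is None:
            continue
        groups.setdefault((oer.family, oer.flank_target), []).append(oer)
    copies = []
    for (family, chrom), members in sorted(groups.items()):
        members.sort(key=lambda o: (o.genomic_site, o.read_id))
        cluster: list[OneEndRead] = []
        for oer in members:
            if cluster and oer.genomic_site - cluster[-1].genomic_site > params.cluster_window:
                copies.append(_make_copy(family, chrom, cluster))
                cluster = []
            cluster.append(oer)
        if cluster:
            copies.append(_make_copy(family, chrom, cluster))
    return copies


def _make_copy(family: str, chrom: str, members: list[OneEndRead]) -> CandidateCopy:
    sites = [o.genomic_site for o in members]
    return CandidateCopy(
        family=family,
        chromosome=chrom,
        site_window=(min(sites), max(sites) + 1),
        supporting_reads=tuple(sorted(o.read_id for o in members)),
        ends_seen=frozenset(o.te_end for o in members),
    )


def scan_insertions(
    segments: Iterable[AlignmentSegment],
    consensus_set: Mapping[str, TransposonConsensus],
    repeat_bed: pd.DataFrame,
    params: ScanParams | None = None,
) -> tuple[list[OneEndRead], list[CandidateCopy], dict]:
    """Full one-end-read analysis: find, classify flanks against the repeat
    annotation, type transposon-flanked reads, cluster unique-flank sites.

    Returns the classified reads, the candidate copies and a summary with
    flank-class and read-type counts.
    """
    params = params or ScanParams()
    oers = find_one_end_reads(segments, consensus_set, params)
    genomic = [o for o in oers if o.flank_class is None]
    if genomic:
        queries = pd.DataFrame(
            [
                (o.flank_target, o.flank_interval[0], o.flank_interval[1], str(i))
                for i, o in enumerate(genomic)
            ],
            columns=["chrom", "start", "end", "name"],
        )
        wao = intersect_repeats(queries, repeat_bed)
    classified: list[OneEndRead] = []
    g_idx = 0
    for oer in oers:
        if oer.flank_class is None:
            overlaps = wao[wao["name"] == str(g_idx)]
            g_idx += 1
            cls = classify_flank(oer, overlaps, consensus_set, params)
            site = oer.genomic_site if cls == FlankClass.UNIQUE else None
            classified.append(replace(oer, flank_class=cls, genomic_site=site))
        else:
            classified.append(oer)
    by_family: dict[str, TransposonConsensus] = dict(consensus_set)
    typed: list[OneEndRead] = []
    for oer in classified:
        if oer.flank_class == FlankClass.SAME_TE:
            typed.extend(type_te_flanked_reads([oer], by_family[oer.family], params))
        else:
            typed.append(oer)
    copies = cluster_copies(typed, params)
    summary = dict(
        n_one_end_reads=len(typed),
        flank_class_counts={
            cls.value: sum(1 for o in typed if o.flank_class == cls) for cls in FlankClass
        },
        fig5d_type_counts={
            t.value: sum(1 for o in typed if o.fig5d_type == t) for t in Fig5dType
        },
        n_candidate_copies=len(copies),
    )
    return typed, copies, summary


def one_end_reads_to_frame(oers: Sequence[OneEndRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                read_id=o.read_id,
                family=o.family,
                te_end=o.te_end,
                te_aligned=o.te_aligned,
                flank_target=o.flank_target,
                flank_start=o.flank_interval[0],
                flank_end=o.flank_interval[1],
                flank_class=o.flank_class.value if o.flank_class else ".",
                genomic_site=o.genomic_site if o.genomic_site is not None else -1,
                fig5d_type=o.fig5d_type.value if o.fig5d_type else ".",
            )
            for o in oers
        ],
        columns=[
            "read_id", "family", "te_end", "te_aligned", "flank_target",
            "flank_start", "flank_end", "flank_class", "genomic_site", "fig5d_type",
        ],
    )


def copies_to_frame(copies: Sequence[CandidateCopy]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                family=c.family,
                chromosome=c.chromosome,
                window_start=c.site_window[0],
                window_end=c.site_window[1],
                n_reads=len(c.supporting_reads),
                ends_seen=",".join(sorted(c.ends_seen)),
                reads=",".join(c.supporting_reads),
            )
            for c in copies
        ],
        columns=[
            "family", "chromosome", "window_start", "window_end",
            "n_reads", "ends_seen", "reads",
        ],
    )
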