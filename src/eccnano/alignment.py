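"""Alignment ingestion and per-read chaining.

Long-read aligners report one read's hits to a repeat consensus as several
primary + supplementary records. This module normalises PAF and SAM records
into :class:`AlignmentSegment` objects whose read coordinates always refer
to the *original* read orientation (the PAF convention; SAM reverse-strand
records are flipped back), then groups them into per-read, per-target
:class:`ReadChain` objects ordered along the read — the substrate for
circle calling and the insertion scan.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .errors import FormatError, ParameterError, ParseError
from .seqio import FastqRead, revcomp

__all__ = [
    "AlignmentSegment",
    "ReadChain",
    "parse_alignments",
    "parse_paf",
    "parse_sam",
    "write_paf",
    "chain_segments",
    "filter_middle_adapter",
]


@dataclass(frozen=True, slots=True)
class AlignmentSegment:
    """One aligned block of one read against one target.

    Read coordinates are on the original read strand, 0-based half-open;
    target coordinates are on the target's forward strand.
    """

    read_id: str
    read_start: int
    read_end: int
    target: str
    target_start: int
    target_end: int
    strand: str = "+"
    mapq: int = 60
    aligned_bases: int = 0
    read_length: int = 0
    target_length: int = 0

    def __post_init__(self) -> None:
        if self.read_start >= self.read_end or self.target_start >= self.target_end:
            raise ParameterError(
                f"{self.read_id}: empty or inverted interval "
                f"read[{self.read_start},{self.read_end}) "
                f"target[{self.target_start},{self.target_end})"
            )
        if self.strand not in "+-":
            raise ParameterError(f"invalid strand {self.strand!r}")
        if self.aligned_bases == 0:
            object.__setattr__(
                self,
                "aligned_bases",
                min(self.read_end - self.read_start, self.target_end - self.target_start),
            )

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass(frozen=True, slots=True)
class ReadChain:
    """All segments of one read on one target, sorted by read_start."""

    read_id: str
    target: str
    segments: tuple[AlignmentSegment, ...]
    total_read_length: int = 0

    def __post_init__(self) -> None:
        if any(s.read_id != self.read_id or s.target != self.target for s in self.segments):
            raise ParameterError("chain segments must share read_id and target")
        ordered = tuple(sorted(self.segments, key=lambda s: (s.read_start, s.read_end)))
        object.__setattr__(self, "segments", ordered)
        if self.total_read_length == 0 and ordered:
            object.__setattr__(
                self,
                "total_read_length",
                max(max(s.read_end for s in ordered), max(s.read_length for s in ordered)),
            )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def aligned_bases(self) -> int:
        return sum(s.aligned_bases for s in self.segments)


def parse_alignments(
    path: str | Path, min_mapq: int = 0, fmt: str | None = None
) -> list[AlignmentSegment]:
    """Read PAF or SAM/BAM alignments; secondary records are dropped.

    ``min_mapq`` of 0 is appropriate against a repeat consensus (multi-mapping
    is intrinsic there); genome alignments normally use a stricter cutoff.
    """
    path = Path(path)
    if fmt is None:
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        suffix = Path(name).suffix.lower()
        fmt = {".paf": "paf", ".sam": "sam", ".bam": "sam"}.get(suffix)
        if fmt is None:
            raise FormatError(f"cannot infer alignment format from {path.name!r}")
    if fmt == "paf":
        segments = parse_paf(path)
    elif fmt == "sam":
        segments = parse_sam(path)
    else:
        raise FormatError(f"unknown alignment format {fmt!r}")
    return [s for s in segments if s.mapq >= min_mapq]


def parse_paf(path: str | Path) -> list[AlignmentSegment]:
    from .seqio import _open_text

    segments = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: PAF needs 12 columns, got {len(fields)}")
            try:
                segments.append(
                    AlignmentSegment(
                        read_id=fields[0],
                        read_length=int(fields[1]),
                        read_start=int(fields[2]),
                        read_end=int(fields[3]),
                        strand=fields[4],
                        target=fields[5],
                        target_length=int(fields[6]),
                        target_start=int(fields[7]),
                        target_end=int(fields[8]),
                        aligned_bases=int(fields[9]),
                        mapq=int(fields[11]),
                    )
                )
            except (ValueError, ParameterError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return segments


def _clips(cigartuples, front: bool) -> int:
    """Total hard+soft clip length at one end of a SAM record."""
    ops = cigartuples if front else reversed(cigartuples)
    total = 0
    for op, length in ops:
        if op in (4, 5):  # S, H
            total += length
        else:
            break
    return total


def parse_sam(path: str | Path) -> list[AlignmentSegment]:
    segments = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary:
                continue
            cig = rec.cigartuples or []
            read_len = rec.infer_read_length() or rec.query_length
            left = _clips(cig, front=True)
            right = _clips(cig, front=False)
            start, end = left, read_len - right
            if rec.is_reverse:
                # SAM stores the reverse-complemented read; map back to the
                # original orientation (the -Y / PAF convention).
                start, end = read_len - end, read_len - start
            aligned = sum(length for op, length in cig if op in (0, 7, 8))  # M, =, X
            segments.append(
                AlignmentSegment(
                    read_id=rec.query_name,
                    read_start=start,
                    read_end=end,
                    target=rec.reference_name,
                    target_start=rec.reference_start,
                    target_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                    aligned_bases=aligned,
                    read_length=read_len,
                    target_length=af.get_reference_length(rec.reference_name)
                    if rec.reference_name in af.references
                    else 0,
                )
            )
    return segments


def write_paf(segments: Iterable[AlignmentSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            block = max(s.read_end - s.read_start, s.target_end - s.target_start)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.read_id,
                        s.read_length or s.read_end,
                        s.read_start,
                        s.read_end,
                        s.strand,
                        s.target,
                        s.target_length or s.target_end,
                        s.target_start,
                        s.target_end,
                        s.aligned_bases,
                        block,
                        s.mapq,
                    )
                )
                + "\n"
            )


def chain_segments(
    segments: Iterable[AlignmentSegment], dominant_only: bool = True
) -> list[ReadChain]:
    """Group segments into per-(read, target) chains sorted along the read.

    With ``dominant_only`` (the default, used for circle calling) a read that
    hits several targets keeps only the target with the largest summed
    aligned bases, so each read votes for exactly one family. Ties break
    lexicographically by target name for determinism.
    """
    by_key: dict[tuple[str, str], list[AlignmentSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.read_id, seg.target), []).append(seg)
    chains = [
        ReadChain(read_id=rid, target=target, segments=tuple(segs))
        for (rid, target), segs in by_key.items()
    ]
    if dominant_only:
        best: dict[str, ReadChain] = {}
        for chain in chains:
            cur = best.get(chain.read_id)
            if (
                cur is None
                or chain.aligned_bases > cur.aligned_bases
                or (chain.aligned_bases == cur.aligned_bases and chain.target < cur.target)
            ):
                best[chain.read_id] = chain
        chains = list(best.values())
    chains.sort(key=lambda c: (c.target, c.read_id))
    return chains


def _adapter_hits(sequence: str, adapter: str, max_mismatches: int) -> list[tuple[int, int]]:
    """Approximate adapter occurrences (start, end) at ≤ max_mismatches edits."""
    import edlib

    hits: list[tuple[int, int]] = []
    for probe in (adapter, revcomp(adapter)):
        res = edlib.align(probe, sequence, mode="HW", task="locations", k=max_mismatches)
        if res["editDistance"] != -1:
            hits.extend((start, end + 1) for start, end in res["locations"])
    return sorted(set(hits))


def filter_middle_adapter(
    reads: Iterable[FastqRead],
    adapter: str,
    max_mismatches: int = 3,
    end_margin: int = 150,
) -> list[FastqRead]:
    """Discard reads with an internal adapter; trim terminal adapter hits.

    A hit whose start lies more than ``end_margin`` from both read ends marks
    a chimeric / mid-ligated read and the whole read is dropped; hits within
    ``end_margin`` of an end are ordinary library adapters and are trimmed.
    Matching allows ``max_mismatches`` edits (substitutions or indels) and
    searches both adapter orientations.
    """
    if not adapter:
        raise ParameterError("adapter sequence must be non-empty")
    kept: list[FastqRead] = []
    for read in reads:
        hits = _adapter_hits(read.sequence, adapter, max_mismatches)
        n = len(read)
        if any(start > end_margin and (n - start) > end_margin for start, end in hits):
            continue
        left = max((end for start, end in hits if start <= end_margin), default=0)
        right = min((start for start, end in hits if (n - start) <= end_margin), default=n)
        if right - left <= 0:
            continue
        if left or right != n:
            read = FastqRead(read.read_id, read.sequence[left:right])
        kept.append(read)
    return kept
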