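"""Synthetic data: circle molecules, rolling-circle reads, planted genomes.

The generator emulates the two sequencing experiments the pipeline serves:

* **Circle sequencing.** Phi29 rolling-circle amplification of a circular
  template yields one long DNA molecule carrying tandem copies of the
  circle; nanopore reads are windows of that concatemer. A read therefore
  starts at a uniformly random rotation of the circle and spans
  ``read_length / circle_size`` monomers. Short debranched fragments are
  removed in the wet protocol, emulated here by a minimum read length.

* **Genomic DNA sequencing.** Reads drawn uniformly from a host genome
  carrying reference transposon copies (optionally nested) and planted
  non-reference copies with target-site duplications.

Every emitted read has one ground-truth row and exact truth alignments
(PAF-writable), so the downstream caller and scanner can be tested without
an external aligner; running a real aligner on the FASTQ is also supported.
Errors are i.i.d. per base (substitution / insertion / deletion).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentSegment, write_paf
from .consensus import CircleType, TransposonConsensus, random_dna
from .errors import ParameterError
from .seqio import FastqRead, revcomp, write_fastq

__all__ = [
    "CircleMolecule",
    "make_circle",
    "make_mito",
    "SimulatedReads",
    "simulate_rca_reads",
    "PlantedGenome",
    "ReferenceCopy",
    "PlantedCopy",
    "plant_insertions",
    "simulate_gdna_reads",
    "divergent_pcr",
]

TRUTH_COLUMNS = [
    "read_id",
    "source",
    "circle_type",
    "family",
    "insertion_site",
    "n_monomers",
    "strand",
]


@dataclass(frozen=True)
class CircleMolecule:
    """A circular DNA molecule whose every base traces to target coordinates.

    ``segments`` lists the target (consensus or mitochondrial reference)
    intervals whose concatenation equals the circle sequence; ``breakpoints``
    records rearrangement join coordinates (empty for full-length types).
    """

    molecule_id: str
    family: str
    circle_type: CircleType
    sequence: str
    target_name: str
    target_length: int
    segments: tuple[tuple[int, int], ...]
    breakpoints: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if sum(e - s for s, e in self.segments) != len(self.sequence):
            raise ParameterError(f"{self.molecule_id}: segments do not tile the circle sequence")

    @property
    def size(self) -> int:
        return len(self.sequence)

    def circle_run_to_target_runs(self, c0: int, c1: int) -> list[tuple[int, int]]:
        """Map a circle-coordinate run [c0, c1) to target-coordinate runs,
        split at rearrangement joins."""
        runs = []
        offset = 0
        for ts, te in self.segments:
            length = te - ts
            lo, hi = max(c0, offset), min(c1, offset + length)
            if lo < hi:
                runs.append((ts + (lo - offset), ts + (hi - offset)))
            offset += length
        return runs

    def ref_interval_to_circle(self, start: int, end: int) -> tuple[int, int] | None:
        """Circle coordinates of a target interval, or None when the interval
        is absent from (or split across joins of) this circle."""
        offset = 0
        for ts, te in self.segments:
            if ts <= start and end <= te:
                return (offset + start - ts, offset + end - ts)
            offset += te - ts
        return None


def make_circle(
    consensus: TransposonConsensus,
    circle_type: CircleType,
    breakpoint: int | None = None,
    seed: int | None = None,
    molecule_id: str | None = None,
) -> CircleMolecule:
    """Build one circle molecule of the requested mechanistic class.

    Full-length classes need no breakpoint. The rearranged classes take a
    breakpoint strictly inside the internal interval (or a seeded random
    one, kept ``margin`` bases clear of the interval ends so the resulting
    circle is unambiguous at the caller's tolerances):

    * ``ONE_LTR_REARRANGED`` — one full LTR plus internal sequence truncated
      at the breakpoint (the auto-integration geometry);
    * ``ZERO_LTR_REARRANGED`` — internal-only fragment from the breakpoint
      to the end of the internal interval, circularised.
    """
    T, L = consensus.length, consensus.ltr_length
    name = consensus.name
    margin = 200
    if circle_type == CircleType.ONE_LTR_FULL:
        seq, segs, bps = consensus.sequence[: T - L], ((0, T - L),), ()
    elif circle_type == CircleType.TWO_LTR_FULL:
        seq, segs, bps = consensus.sequence, ((0, T),), ()
    elif circle_type in (CircleType.ONE_LTR_REARRANGED, CircleType.ZERO_LTR_REARRANGED):
        lo, hi = L + margin, T - L - margin
        if breakpoint is None:
            if hi <= lo:
                raise ParameterError(f"{name}: internal interval too short for a rearrangement")
            breakpoint = int(np.random.default_rng(seed).integers(lo, hi))
        if not (L < breakpoint < T - L):
            raise ParameterError(
                f"breakpoint {breakpoint} must lie strictly inside the internal "
                f"interval [{L}, {T - L}) — rearrangement joins cannot fall in an LTR"
            )
        if circle_type == CircleType.ONE_LTR_REARRANGED:
            seq, segs = consensus.sequence[:breakpoint], ((0, breakpoint),)
        else:
            seq, segs = consensus.sequence[breakpoint : T - L], ((breakpoint, T - L),)
        bps = (breakpoint,)
    else:
        raise ParameterError(f"cannot construct a transposon circle of type {circle_type}")
    return CircleMolecule(
        molecule_id=molecule_id or f"{name}:{circle_type.value}",
        family=name,
        circle_type=circle_type,
        sequence=seq,
        target_name=name,
        target_length=T,
        segments=segs,
        breakpoints=bps,
    )


def make_mito(
    name: str = "mito", length: int = 19500, gc: float = 0.21, seed: int = 0
) -> CircleMolecule:
    """Mitochondrial circle used as the per-sample normalisation control.

    Defaults approximate the fly mitochondrial genome (~19.5 kb, AT-rich).
    """
    seq = random_dna(length, gc, np.random.default_rng(seed))
    return CircleMolecule(
        molecule_id=name,
        family=name,
        circle_type=CircleType.MITO,
        sequence=seq,
        target_name=name,
        target_length=length,
        segments=((0, length),),
    )


# ---------------------------------------------------------------------------
# per-base error model

_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_BASES_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)


def mutate_sequence(
    seq: str, error_rates: tuple[float, float, float], rng: np.random.Generator
) -> str:
    """Apply i.i.d. per-base substitutions, insertions and deletions."""
    p_sub, p_ins, p_del = error_rates
    if p_sub == p_ins == p_del == 0 or not seq:
        return seq
    idx = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    n = idx.size
    sub_mask = rng.random(n) < p_sub
    if sub_mask.any():
        idx[sub_mask] = (idx[sub_mask] + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4
    draws = rng.random(n)
    counts = np.ones(n, dtype=np.int64)
    counts[draws < p_del] = 0
    counts[(draws >= p_del) & (draws < p_del + p_ins)] = 2
    rep = np.repeat(np.arange(n), counts)
    out = idx[rep]
    dup = np.flatnonzero(np.diff(rep) == 0) + 1
    if dup.size:
        out[dup] = rng.integers(0, 4, size=dup.size)
    return _BASES_U8[out].tobytes().decode()


def _check_error_rates(error_rates: tuple[float, float, float]) -> None:
    if len(error_rates) != 3 or any(not (0 <= r < 1) for r in error_rates):
        raise ParameterError(f"error rates must be three fractions in [0, 1), got {error_rates}")


def _lognormal_length(rng: np.random.Generator, mean: float, sigma: float) -> int:
    """Read length from a log-normal with the stated arithmetic mean."""
    if sigma == 0:
        return int(round(mean))
    mu = np.log(mean) - sigma**2 / 2
    return max(1, int(round(rng.lognormal(mu, sigma))))


@dataclass
class SimulatedReads:
    """Reads plus per-read ground truth and exact truth alignments."""

    reads: list[FastqRead]
    truth: pd.DataFrame
    alignments: list[AlignmentSegment]
    n_discarded: int = 0

    def write(
        self,
        fastq_path: str | Path,
        truth_path: str | Path | None = None,
        paf_path: str | Path | None = None,
    ) -> None:
        write_fastq(self.reads, fastq_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)
        if paf_path is not None:
            write_paf(self.alignments, paf_path)


# segments shorter than this are kept in the read sequence but not emitted
# as truth alignments (a real aligner would not report them either)
_MIN_TRUTH_SEGMENT = 10


def simulate_rca_reads(
    molecules: Sequence[CircleMolecule],
    n_reads: int,
    mean_read_length: int = 8000,
    min_read_length: int = 1000,
    error_rates: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    weights: Sequence[float] | None = None,
    length_sigma: float = 0.6,
    both_strands: bool = True,
    read_prefix: str = "r",
) -> SimulatedReads:
    """Simulate nanopore reads of rolling-circle-amplified circle molecules.

    Each of ``n_reads`` attempts picks a molecule (by ``weights``), draws a
    log-normal read length with the stated mean, starts at a uniform
    rotation of the circle and walks tandem monomers; attempts shorter than
    ``min_read_length`` are discarded, emulating the removal of short
    debranched fragments. Monomer copy number per read is therefore implied
    by read length / circle size, never sampled separately.
    """
    if not molecules:
        raise ParameterError("at least one circle molecule is required")
    if n_reads <= 0:
        raise ParameterError(f"n_reads must be positive, got {n_reads}")
    _check_error_rates(error_rates)
    w = np.full(len(molecules), 1 / len(molecules)) if weights is None else np.asarray(weights, float)
    if w.size != len(molecules) or (w < 0).any() or w.sum() == 0:
        raise ParameterError("weights must be non-negative and match molecules")
    w = w / w.sum()

    rng = np.random.default_rng(seed)
    reads: list[FastqRead] = []
    truth_rows = []
    alignments: list[AlignmentSegment] = []
    n_discarded = 0
    for i in range(n_reads):
        mol = molecules[int(rng.choice(len(molecules), p=w))]
        S = mol.size
        read_len = _lognormal_length(rng, mean_read_length, length_sigma)
        if read_len < min_read_length:
            n_discarded += 1
            continue
        rotation = int(rng.integers(S))
        strand = "+" if not both_strands or rng.random() < 0.5 else "-"
        read_id = f"{read_prefix}{i:06d}"

        # circle-coordinate runs of the concatemer window
        circle_runs = []
        pos, remaining = rotation, read_len
        while remaining > 0:
            step = min(S - pos, remaining)
            circle_runs.append((pos, pos + step))
            remaining -= step
            pos = 0

        pieces: list[str] = []
        plus_segments: list[tuple[int, int, int, int]] = []  # read/target intervals
        offset = 0
        for c0, c1 in circle_runs:
            cpos = c0  # target runs tile [c0, c1) in order
            for ts, te in mol.circle_run_to_target_runs(c0, c1):
                piece = mutate_sequence(mol.sequence[cpos : cpos + (te - ts)], error_rates, rng)
                cpos += te - ts
                if len(piece) and (te - ts) >= _MIN_TRUTH_SEGMENT:
                    plus_segments.append((offset, offset + len(piece), ts, te))
                pieces.append(piece)
                offset += len(piece)
        seq = "".join(pieces)
        total = len(seq)
        if strand == "-":
            seq = revcomp(seq)
            plus_segments = [(total - re, total - rs, ts, te) for rs, re, ts, te in plus_segments]
        for rs, re, ts, te in plus_segments:
            alignments.append(
                AlignmentSegment(
                    read_id=read_id,
                    read_start=rs,
                    read_end=re,
                    target=mol.target_name,
                    target_start=ts,
                    target_end=te,
                    strand=strand,
                    mapq=60,
                    aligned_bases=te - ts,
                    read_length=total,
                    target_length=mol.target_length,
                )
            )
        reads.append(FastqRead(read_id, seq))
        truth_rows.append(
            (read_id, mol.molecule_id, mol.circle_type.value, mol.family, pd.NA,
             read_len / S, strand)
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedReads(reads=reads, truth=truth, alignments=alignments, n_discarded=n_discarded)


# ---------------------------------------------------------------------------
# host genomes with planted insertions


@dataclass(frozen=True)
class ReferenceCopy:
    """A transposon copy present in the reference assembly."""

    family: str
    start: int  # reference coordinates, half-open
    end: int
    nested: bool = False


@dataclass(frozen=True)
class PlantedCopy:
    """A non-reference copy inserted into the sample at ``site`` with a
    target-site duplication of ``tsd_length`` bases."""

    family: str
    site: int  # reference coordinate of the insertion point
    tsd_length: int


@dataclass
class PlantedGenome:
    """Reference genome plus the sample's planted non-reference copies.

    ``sequence`` is the *reference* (alignment target). The sample genome —
    the molecule reads are drawn from — is the reference with each planted
    copy inserted at its site followed by a duplication of the
    ``tsd_length`` bases preceding the site.
    """

    chrom: str
    sequence: str
    consensus_set: dict[str, TransposonConsensus]
    reference_copies: list[ReferenceCopy]
    planted_copies: list[PlantedCopy]
    repeat_bed: pd.DataFrame
    # reference intervals annotated with consensus coordinates; nested outer
    # copies contribute two pieces around the inner copy
    te_pieces: list[tuple[int, int, str, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sample_blocks(self) -> list[dict]:
        """Disjoint blocks tiling the sample genome, each mapping back to
        reference and/or consensus coordinates (segment boundaries of an
        ideal aligner). Reference blocks are further split at reference-copy
        piece boundaries so every block has a single consensus mapping."""
        cuts = sorted({0, self.length, *(p.site for p in self.planted_copies)})
        piece_bounds = sorted({b for s, e, _, _ in self.te_pieces for b in (s, e)})
        blocks: list[dict] = []
        sample_pos = 0

        def add_ref_run(r0: int, r1: int) -> None:
            nonlocal sample_pos
            bounds = [r0] + [b for b in piece_bounds if r0 < b < r1] + [r1]
            for a, b in zip(bounds, bounds[1:]):
                te = next(
                    ((fam, t0 + (a - s)) for s, e, fam, t0 in self.te_pieces if s <= a and b <= e),
                    None,
                )
                blocks.append(
                    dict(sample_start=sample_pos, sample_end=sample_pos + (b - a),
                         ref_start=a, ref_end=b, te=te, site=None)
                )
                sample_pos += b - a

        prev = 0
        for copy in sorted(self.planted_copies, key=lambda p: p.site):
            add_ref_run(prev, copy.site)
            cons = self.consensus_set[copy.family]
            blocks.append(
                dict(sample_start=sample_pos, sample_end=sample_pos + cons.length,
                     ref_start=None, ref_end=None, te=(copy.family, 0), site=copy.site)
            )
            sample_pos += cons.length
            prev = copy.site - copy.tsd_length  # target-site duplication
        add_ref_run(prev, self.length)
        return blocks

    def sample_sequence(self) -> str:
        parts = []
        for blk in self.sample_blocks():
            if blk["ref_start"] is not None:
                parts.append(self.sequence[blk["ref_start"] : blk["ref_end"]])
            else:
                fam, t0 = blk["te"]
                cons = self.consensus_set[fam]
                parts.append(cons.sequence[t0 : t0 + (blk["sample_end"] - blk["sample_start"])])
        return "".join(parts)


def plant_insertions(
    genome_length: int,
    consensus: TransposonConsensus,
    n_reference: int = 2,
    n_planted: int = 3,
    nested: bool = False,
    repeat_fraction: float = 0.1,
    seed: int = 0,
    tsd_length: int = 4,
    gc: float = 0.42,
    chrom: str = "chr1",
    margin: int = 8000,
) -> PlantedGenome:
    """Build a reference genome with transposon copies and plant new ones.

    The reference carries ``n_reference`` full-length copies (with
    ``nested`` the first two form an outer copy interrupted by an inner one,
    the geometry that mimics 1-LTR-rearranged junctions in genomic reads);
    ``n_planted`` full-length non-reference copies are assigned insertion
    sites in unique sequence, each with a ``tsd_length`` bp target-site
    duplication. The repeat BED covers every transposon copy plus random
    decoy repeats totalling ``repeat_fraction`` of the genome. Planted
    sites are kept well apart (≥ ``margin``) and clear of repeats so that a
    junction-spanning read has unique flanking sequence.
    """
    T = consensus.length
    n_copies = n_reference + n_planted
    if n_copies * T >= genome_length:
        raise ParameterError(
            f"{n_copies} copies of {T} bp exceed the {genome_length} bp genome"
        )
    if nested and n_reference < 2:
        raise ParameterError("nesting requires at least two reference copies")
    rng = np.random.default_rng(seed)
    backbone = random_dna(genome_length, gc, rng)

    # reference inserts: a nested pair consumes two copies
    inserts: list[tuple[str, bool]] = []  # (sequence, is_nested_pair)
    mid = T // 2  # inner insertion point, inside the internal interval
    n_plain = n_reference
    if nested:
        inserts.append((consensus.sequence[:mid] + consensus.sequence + consensus.sequence[mid:], True))
        n_plain -= 2
    inserts.extend((consensus.sequence, False) for _ in range(n_plain))

    positions = _spaced_positions(rng, len(inserts), genome_length, margin)
    ref_parts, reference_copies, te_pieces = [], [], []
    prev, shift = 0, 0
    for pos, (ins_seq, is_nested) in zip(positions, inserts):
        ref_parts.append(backbone[prev:pos])
        start = pos + shift
        if is_nested:
            reference_copies.append(ReferenceCopy(consensus.name, start, start + 2 * T, False))
            reference_copies.append(
                ReferenceCopy(consensus.name, start + mid, start + mid + T, True)
            )
            te_pieces += [
                (start, start + mid, consensus.name, 0),
                (start + mid, start + mid + T, consensus.name, 0),
                (start + mid + T, start + 2 * T, consensus.name, mid),
            ]
        else:
            reference_copies.append(ReferenceCopy(consensus.name, start, start + T, False))
            te_pieces.append((start, start + T, consensus.name, 0))
        ref_parts.append(ins_seq)
        shift += len(ins_seq)
        prev = pos
    ref_parts.append(backbone[prev:])
    sequence = "".join(ref_parts)
    ref_len = len(sequence)

    # repeat annotation: every copy interval plus random decoys
    copy_ivs = sorted((c.start, c.end) for c in reference_copies if not c.nested)
    repeat_rows = [(chrom, s, e, consensus.name) for s, e in copy_ivs]
    decoy_target = int(repeat_fraction * ref_len)
    covered, tries = 0, 0
    decoys: list[tuple[int, int]] = []
    while covered < decoy_target and tries < 10000:
        tries += 1
        length = int(rng.integers(300, 1500))
        start = int(rng.integers(0, ref_len - length))
        iv = (start, start + length)
        if any(_overlap(iv, (s - 500, e + 500)) for s, e in copy_ivs + decoys):
            continue
        decoys.append(iv)
        repeat_rows.append((chrom, iv[0], iv[1], f"decoy_repeat_{len(decoys)}"))
        covered += length
    repeat_bed = (
        pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "name"])
        .sort_values(["chrom", "start", "end"])
        .reset_index(drop=True)
    )

    # planted sites: unique sequence, well separated
    forbidden = [(s - margin, e + margin) for s, e in copy_ivs] + [
        (s - 2000, e + 2000) for s, e in decoys
    ]
    planted_copies = []
    sites: list[int] = []
    tries = 0
    while len(sites) < n_planted and tries < 100000:
        tries += 1
        site = int(rng.integers(margin, ref_len - margin))
        if any(lo <= site < hi for lo, hi in forbidden):
            continue
        if any(abs(site - s) < margin for s in sites):
            continue
        sites.append(site)
    if len(sites) < n_planted:
        raise ParameterError("genome too crowded to place the requested planted copies")
    for site in sorted(sites):
        planted_copies.append(PlantedCopy(consensus.name, site, tsd_length))

    return PlantedGenome(
        chrom=chrom,
        sequence=sequence,
        consensus_set={consensus.name: consensus},
        reference_copies=reference_copies,
        planted_copies=planted_copies,
        repeat_bed=repeat_bed,
        te_pieces=te_pieces,
    )


def _spaced_positions(
    rng: np.random.Generator, n: int, genome_length: int, margin: int
) -> list[int]:
    positions: list[int] = []
    tries = 0
    while len(positions) < n and tries < 100000:
        tries += 1
        pos = int(rng.integers(margin, genome_length - margin))
        if all(abs(pos - p) >= margin for p in positions):
            positions.append(pos)
    if len(positions) < n:
        raise ParameterError("cannot place insertions with the requested spacing")
    return sorted(positions)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def simulate_gdna_reads(
    genome: PlantedGenome,
    n_reads: int,
    mean_read_length: int = 8000,
    min_read_length: int = 500,
    error_rates: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    length_sigma: float = 0.6,
    both_strands: bool = True,
    end_min: int = 1000,
    flank_min: int = 200,
) -> SimulatedReads:
    """Simulate genomic reads from the sample genome (reference + planted).

    Truth marks whether each read spans a planted-copy junction with at
    least ``end_min`` transposon bases and ``flank_min`` flanking genomic
    bases — the geometry the one-end-read scan requires. Truth alignments
    cover both targets: reference blocks map to the chromosome (planted
    copies interrupt them, producing split reads) and every transposon base
    maps to its consensus.
    """
    if n_reads <= 0:
        raise ParameterError(f"n_reads must be positive, got {n_reads}")
    _check_error_rates(error_rates)
    rng = np.random.default_rng(seed)
    blocks = genome.sample_blocks()
    sample_seq = genome.sample_sequence()
    G = len(sample_seq)
    block_starts = np.array([b["sample_start"] for b in blocks])

    # planted junction geometry in sample coordinates
    planted_spans = []  # (te_start, te_end, site)
    for blk in blocks:
        if blk["site"] is not None:
            planted_spans.append((blk["sample_start"], blk["sample_end"], blk["site"]))

    reads, truth_rows, alignments = [], [], []
    n_discarded = 0
    for i in range(n_reads):
        read_len = _lognormal_length(rng, mean_read_length, length_sigma)
        a = int(rng.integers(0, G))
        b = min(a + read_len, G)
        if b - a < min_read_length:
            n_discarded += 1
            continue
        strand = "+" if not both_strands or rng.random() < 0.5 else "-"
        read_id = f"g{i:06d}"

        # decompose [a, b) into block runs, mutate per run
        runs = []  # (read_start, read_end, block, run_ref/te offsets)
        offset = 0
        pieces = []
        k = int(np.searchsorted(block_starts, a, side="right")) - 1
        pos = a
        while pos < b:
            blk = blocks[k]
            hi = min(b, blk["sample_end"])
            piece = mutate_sequence(sample_seq[pos:hi], error_rates, rng)
            runs.append(dict(rs=offset, re=offset + len(piece), blk=blk, lo=pos, hi=hi))
            pieces.append(piece)
            offset += len(piece)
            pos = hi
            k += 1
        seq = "".join(pieces)
        total = len(seq)

        # genome segments: merge consecutive runs contiguous in ref coords
        gsegs = []
        for run in runs:
            blk = run["blk"]
            if blk["ref_start"] is None:
                continue
            r0 = blk["ref_start"] + (run["lo"] - blk["sample_start"])
            r1 = blk["ref_start"] + (run["hi"] - blk["sample_start"])
            if gsegs and gsegs[-1][3] == r0 and gsegs[-1][1] == run["rs"]:
                prev_ = gsegs.pop()
                gsegs.append((prev_[0], run["re"], prev_[2], r1))
            else:
                gsegs.append((run["rs"], run["re"], r0, r1))
        # consensus segments: merge runs contiguous in te coords & same family
        tsegs = []  # (rs, re, family, t0, t1)
        for run in runs:
            blk = run["blk"]
            if blk["te"] is None:
                continue
            fam, t_off = blk["te"]
            t0 = t_off + (run["lo"] - blk["sample_start"])
            t1 = t_off + (run["hi"] - blk["sample_start"])
            if tsegs and tsegs[-1][2] == fam and tsegs[-1][4] == t0 and tsegs[-1][1] == run["rs"]:
                prev_ = tsegs.pop()
                tsegs.append((prev_[0], run["re"], fam, prev_[3], t1))
            else:
                tsegs.append((run["rs"], run["re"], fam, t0, t1))

        if strand == "-":
            seq = revcomp(seq)
            gsegs = [(total - re, total - rs, g0, g1) for rs, re, g0, g1 in gsegs]
            tsegs = [(total - re, total - rs, fam, t0, t1) for rs, re, fam, t0, t1 in tsegs]

        for rs, re, g0, g1 in gsegs:
            if g1 - g0 < _MIN_TRUTH_SEGMENT or re - rs <= 0:
                continue
            alignments.append(
                AlignmentSegment(
                    read_id=read_id, read_start=rs, read_end=re, target=genome.chrom,
                    target_start=g0, target_end=g1, strand=strand, mapq=60,
                    aligned_bases=g1 - g0, read_length=total, target_length=genome.length,
                )
            )
        for rs, re, fam, t0, t1 in tsegs:
            if t1 - t0 < _MIN_TRUTH_SEGMENT or re - rs <= 0:
                continue
            alignments.append(
                AlignmentSegment(
                    read_id=read_id, read_start=rs, read_end=re, target=fam,
                    target_start=t0, target_end=t1, strand=strand, mapq=60,
                    aligned_bases=t1 - t0, read_length=total,
                    target_length=genome.consensus_set[fam].length,
                )
            )

        insertion_site: int | None = None
        for ts, te, site in planted_spans:
            left = a <= ts - flank_min and min(b, te) - ts >= end_min
            right = b >= te + flank_min and te - max(a, ts) >= end_min
            if left or right:
                insertion_site = site
                break
        reads.append(FastqRead(read_id, seq))
        truth_rows.append(
            (read_id, genome.chrom, "none", "genome",
             insertion_site if insertion_site is not None else pd.NA, 0.0, strand)
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedReads(reads=reads, truth=truth, alignments=alignments, n_discarded=n_discarded)


# ---------------------------------------------------------------------------
# in-silico divergent PCR


def divergent_pcr(
    template: CircleMolecule | str,
    fwd_3prime: int,
    rev_3prime: int,
    reference: TransposonConsensus | str,
    primer_length: int = 20,
) -> int | None:
    """Predict the product of an outward-facing (divergent) primer pair.

    Primers are given by the template-reference coordinate of their 3' end:
    the forward primer extends toward increasing coordinates from
    ``fwd_3prime``, the reverse primer toward decreasing coordinates from
    ``rev_3prime``. Divergent geometry requires the forward primer to lie
    right of the reverse primer on the linear reference (3' ends pointing
    away from each other); a convergent pair is ordinary PCR and is
    rejected. On a linear template no extension path joins the primers and
    the result is ``None``; on a circle whose sequence contains both primer
    footprints the product walks each primer's extension direction across
    the circle junction and its exact length is returned.
    """
    ref_seq = reference.sequence if isinstance(reference, TransposonConsensus) else reference
    k = primer_length
    f_iv = (fwd_3prime - k + 1, fwd_3prime + 1)
    r_iv = (rev_3prime, rev_3prime + k)
    if f_iv[0] < 0 or r_iv[1] > len(ref_seq):
        raise ParameterError("primer footprint outside the reference sequence")
    if f_iv[0] < r_iv[1]:
        raise ParameterError(
            "primers face each other (convergent) — that is ordinary PCR, not divergent"
        )
    if not isinstance(template, CircleMolecule):
        return None
    fc = template.ref_interval_to_circle(*f_iv)
    rc = template.ref_interval_to_circle(*r_iv)
    if fc is None or rc is None:
        return None  # a primer site is absent from this circle
    S = template.size
    product = (rc[1] - fc[0]) % S
    return S if product == 0 else product
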