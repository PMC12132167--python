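"""Transposon consensus sequences and circle-type vocabulary.

An LTR retrotransposon consensus is a linear sequence of length T carrying
two byte-identical long terminal repeats (LTRs) of length L at its ends:

    [ 5' LTR | internal sequence | 3' LTR ]
      [0, L)      [L, T-L)        [T-L, T)

The identity of the two LTRs is what makes circle-junction geometry
informative: an aligner may place the shared LTR bases of a junction on
either flank, so downstream classification works on a placement-invariant
junction statistic rather than raw overlap.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, ParameterError
from .seqio import read_fasta, write_fasta

__all__ = [
    "CircleType",
    "TransposonConsensus",
    "build_consensus",
    "random_dna",
    "load_consensus_set",
    "write_consensus_set",
]


class CircleType(str, enum.Enum):
    """Mechanistic classes of retrotransposon extrachromosomal circles.

    ONE_LTR_FULL   circle of one LTR plus the complete internal sequence,
                   the ligation product that follows second-strand synthesis;
    TWO_LTR_FULL   circle of the entire element, end-joining of the
                   full-length linear cDNA;
    ONE_LTR_REARRANGED  one intact LTR joined into internal sequence,
                   the auto-integration product;
    ZERO_LTR_REARRANGED circularised internal fragment with no intact LTR;
    MITO           mitochondrial circle used as a normalisation control.

    NOT_CIRCULAR and AMBIGUOUS are caller verdicts, never simulated classes.
    """

    ONE_LTR_FULL = "one_ltr_full"
    TWO_LTR_FULL = "two_ltr_full"
    ONE_LTR_REARRANGED = "one_ltr_rearranged"
    ZERO_LTR_REARRANGED = "zero_ltr_rearranged"
    MITO = "mito"
    NOT_CIRCULAR = "not_circular"
    AMBIGUOUS = "ambiguous"


#: classes a simulated circle molecule may take
MOLECULE_TYPES = (
    CircleType.ONE_LTR_FULL,
    CircleType.TWO_LTR_FULL,
    CircleType.ONE_LTR_REARRANGED,
    CircleType.ZERO_LTR_REARRANGED,
    CircleType.MITO,
)


@dataclass(frozen=True)
class TransposonConsensus:
    """A named consensus with annotated identical 5'/3' LTRs."""

    name: str
    sequence: str
    ltr_length: int

    def __post_init__(self) -> None:
        T, L = len(self.sequence), self.ltr_length
        if L <= 0:
            raise ParameterError(f"{self.name}: ltr_length must be positive, got {L}")
        if 2 * L >= T:
            raise ParameterError(f"{self.name}: 2*ltr_length ({2 * L}) must be < length ({T})")
        if self.sequence[:L] != self.sequence[T - L :]:
            raise ConfigurationError(f"{self.name}: 5' and 3' LTR sequences differ")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ltr5(self) -> tuple[int, int]:
        return (0, self.ltr_length)

    @property
    def ltr3(self) -> tuple[int, int]:
        return (self.length - self.ltr_length, self.length)

    @property
    def internal(self) -> tuple[int, int]:
        return (self.ltr_length, self.length - self.ltr_length)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with the given GC content."""
    if not 0 < gc < 1:
        raise ParameterError(f"gc must be in (0, 1), got {gc}")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def build_consensus(
    name: str,
    internal_length: int,
    ltr_length: int,
    gc: float = 0.45,
    seed: int = 0,
) -> TransposonConsensus:
    """Construct a synthetic consensus with byte-identical terminal repeats.

    Total length is ``internal_length + 2 * ltr_length``; the 3' LTR is a
    copy of the 5' LTR, deterministic for a given seed.
    """
    if internal_length <= 0 or ltr_length <= 0:
        raise ParameterError("internal_length and ltr_length must be positive")
    rng = np.random.default_rng(seed)
    ltr = random_dna(ltr_length, gc, rng)
    internal = random_dna(internal_length, gc, rng)
    return TransposonConsensus(name=name, sequence=ltr + internal + ltr, ltr_length=ltr_length)


def load_consensus_set(
    fasta_path: str | Path, ltr_annotation: dict[str, int] | str | Path
) -> dict[str, TransposonConsensus]:
    """Load consensus FASTA plus an LTR annotation (name→ltr_length mapping
    or a two-column TSV of the same)."""
    seqs = read_fasta(fasta_path)
    if not isinstance(ltr_annotation, dict):
        ann: dict[str, int] = {}
        with open(ltr_annotation) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                ann[name] = int(length)
        ltr_annotation = ann
    out = {}
    for name, ltr_len in ltr_annotation.items():
        if name not in seqs:
            raise ConfigurationError(f"LTR annotation names {name!r} absent from FASTA")
        out[name] = TransposonConsensus(name=name, sequence=seqs[name], ltr_length=ltr_len)
    return out


def write_consensus_set(
    consensus_set: dict[str, TransposonConsensus],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    write_fasta({c.name: c.sequence for c in consensus_set.values()}, fasta_path)
    with open(annotation_path, "w") as fh:
        for c in consensus_set.values():
            fh.write(f"{c.name}\t{c.ltr_length}\n")
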