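"""Plain-text sequence and interval I/O.

FASTA/FASTQ go through Biopython; PAF, BED and BedGraph are simple
tab-separated conventions written/validated here. All interval formats are
0-based, half-open.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

__all__ = [
    "FastqRead",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]

# constant placeholder quality (Q20); no stage consumes base qualities
_QUAL_CHAR = "5"

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class FastqRead:
    """One sequencing read; quality is a constant placeholder when simulated."""

    read_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [FastqRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{_QUAL_CHAR * len(read.sequence)}\n")


def iter_fastq(path: str | Path) -> Iterator[FastqRead]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield FastqRead(rec.id, str(rec.seq).upper())


BED_COLUMNS = ["chrom", "start", "end", "name"]


def read_bed(path: str | Path, require_sorted: bool = True) -> pd.DataFrame:
    """Read a 3+ column BED file into a DataFrame (chrom, start, end, name).

    Raises :class:`ParseError` on invalid intervals or, when
    ``require_sorted``, on coordinate-unsorted input within a chromosome.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else "."
            rows.append((fields[0], start, end, name))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if require_sorted and len(df) > 1:
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ParseError(f"{path}: intervals on {chrom} are not coordinate-sorted")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.sort_values(["chrom", "start", "end"])[cols].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """Write (chrom, start, end, depth) runs as BedGraph."""
    df[["chrom", "start", "end", "depth"]].to_csv(path, sep="\t", header=False, index=False)
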