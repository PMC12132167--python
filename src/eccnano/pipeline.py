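"""End-to-end pipeline drivers: ingest → call → quantify / scan.

Both pipelines consume precomputed alignments (the generator's truth PAF or
any long-read aligner's PAF/SAM); alignment itself is pluggable and never
required. All outputs are plain-text (TSV / JSON / BedGraph) and
byte-deterministic for a given config, so re-running a config reproduces
the run exactly.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alignment import chain_segments, parse_alignments
from .caller import CallerParams, CircleType, call_circles, calls_to_frame, summarize_calls
from .consensus import load_consensus_set
from .errors import ConfigurationError
from .insertions import ScanParams, copies_to_frame, one_end_reads_to_frame, scan_insertions
from .quantify import coverage_track, fold_change, mito_normalize
from .seqio import read_bed, write_bedgraph

__all__ = ["SampleSpec", "RunConfig", "run_ecdna_pipeline", "run_insertion_pipeline"]

logger = logging.getLogger("eccnano")

CIRCULAR_TYPES = frozenset(
    t.value
    for t in (
        CircleType.ONE_LTR_FULL,
        CircleType.TWO_LTR_FULL,
        CircleType.ONE_LTR_REARRANGED,
        CircleType.ZERO_LTR_REARRANGED,
    )
)


@dataclass
class SampleSpec:
    """One sequencing sample: a name, its condition label and alignments."""

    name: str
    condition: str
    alignments: str


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``control_condition`` / ``treatment_condition`` name the two condition
    labels compared by the fold-change step; with exactly two conditions
    present they default to lexicographic order.
    """

    mode: str  # "ecdna" or "insertion"
    samples: list[SampleSpec]
    consensus_fasta: str
    ltr_annotation: str | dict[str, int]
    outdir: str
    seed: int = 0
    mito_name: str | None = None
    repeat_bed: str | None = None
    control_condition: str | None = None
    treatment_condition: str | None = None
    genome_min_mapq: int = 20
    caller: CallerParams = field(default_factory=CallerParams)
    scan: ScanParams = field(default_factory=ScanParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ConfigurationError("config must set an explicit seed")
        raw["samples"] = [SampleSpec(**s) for s in raw.get("samples", [])]
        if "caller" in raw:
            raw["caller"] = CallerParams(**raw["caller"])
        if "scan" in raw:
            raw["scan"] = ScanParams(**raw["scan"])
        return cls(**raw)

    def validate(self) -> None:
        if self.mode not in ("ecdna", "insertion"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not self.samples:
            raise ConfigurationError("at least one sample is required")
        if not Path(self.consensus_fasta).exists():
            raise ConfigurationError(f"consensus FASTA not found: {self.consensus_fasta}")
        if isinstance(self.ltr_annotation, str) and not Path(self.ltr_annotation).exists():
            raise ConfigurationError(f"LTR annotation not found: {self.ltr_annotation}")
        for sample in self.samples:
            if not Path(sample.alignments).exists():
                raise ConfigurationError(
                    f"sample {sample.name}: alignments not found: {sample.alignments}"
                )
        if self.mode == "insertion":
            if self.repeat_bed is None or not Path(self.repeat_bed).exists():
                raise ConfigurationError("insertion mode requires an existing repeat_bed")

    def echo(self) -> dict:
        cfg = asdict(self)
        return cfg


def _log_params(config: RunConfig) -> None:
    for key, value in sorted(config.echo().items()):
        logger.info("config %s = %r", key, value)


def run_ecdna_pipeline(config: RunConfig) -> dict:
    """Circle calling and quantification across all configured samples.

    Per sample: parse alignments, call circles against the consensus set,
    count mitochondrial reads, normalize family abundances. Across
    samples: fold change + Welch t-test between the two conditions. Writes
    circle_calls.<sample>.tsv, coverage.<sample>.<family>.bedgraph,
    abundance.tsv, fold_change.tsv and summary.json under ``outdir``.
    """
    config.validate()
    _log_params(config)
    consensus_set = load_consensus_set(config.consensus_fasta, config.ltr_annotation)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    extra = {config.mito_name} if config.mito_name else set()

    abundance_frames = []
    summary: dict = {"samples": {}}
    for sample in config.samples:
        segments = parse_alignments(sample.alignments, min_mapq=0)
        calls = call_circles(segments, consensus_set, config.caller, extra_targets=extra)
        calls_to_frame(calls).to_csv(
            outdir / f"circle_calls.{sample.name}.tsv", sep="\t", index=False
        )
        chains = chain_segments(segments, dominant_only=True)
        mito_reads = sum(1 for c in chains if c.target == config.mito_name)
        counts: dict[str, int] = {name: 0 for name in consensus_set}
        n_ambiguous = 0
        for call in calls:
            if call.circle_type.value in CIRCULAR_TYPES:
                counts[call.family] += 1
            elif call.circle_type == CircleType.AMBIGUOUS:
                n_ambiguous += 1
        if config.mito_name:
            abundance_frames.append(
                mito_normalize(counts, mito_reads, sample=sample.name).assign(
                    condition=sample.condition
                )
            )
        sample_summary = summarize_calls(calls)
        sample_summary["_mito_reads"] = mito_reads
        sample_summary["_ambiguous_other"] = n_ambiguous
        summary["samples"][sample.name] = sample_summary
        for family in consensus_set:
            fam_segments = [
                s
                for c in chains
                if c.target == family
                for s in c.segments
            ]
            if fam_segments:
                _, bedgraph = coverage_track(fam_segments, consensus_set[family])
                write_bedgraph(
                    bedgraph, outdir / f"coverage.{sample.name}.{family}.bedgraph"
                )

    if abundance_frames:
        abundance = pd.concat(abundance_frames, ignore_index=True)
        abundance.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        conditions = sorted(abundance["condition"].unique())
        ctrl_label = config.control_condition
        treat_label = config.treatment_condition
        if ctrl_label is None and len(conditions) == 2:
            ctrl_label, treat_label = conditions
        if ctrl_label is not None and treat_label is not None:
            fc = fold_change(
                abundance[abundance["condition"] == ctrl_label],
                abundance[abundance["condition"] == treat_label],
            )
            fc.to_csv(outdir / "fold_change.tsv", sep="\t", index=False)
            summary["fold_change"] = {
                row["family"]: dict(
                    log2fc=row["log2fc"], fold_change=row["fold_change"], p_value=row["p_value"]
                )
                for _, row in fc.iterrows()
            }
    summary["config"] = config.echo()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def run_insertion_pipeline(config: RunConfig) -> dict:
    """One-end-read insertion scan across all configured samples.

    Genome alignments below ``genome_min_mapq`` are dropped (consensus
    alignments keep mapq 0: repeat consensus mapping is inherently
    multi-mapping). Writes one_end_reads.<sample>.tsv,
    candidate_copies.<sample>.tsv and summary.json under ``outdir``.
    """
    config.validate()
    _log_params(config)
    consensus_set = load_consensus_set(config.consensus_fasta, config.ltr_annotation)
    repeat_bed = read_bed(config.repeat_bed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"samples": {}}
    for sample in config.samples:
        segments = parse_alignments(sample.alignments, min_mapq=0)
        segments = [
            s
            for s in segments
            if s.target in consensus_set or s.mapq >= config.genome_min_mapq
        ]
        oers, copies, sample_summary = scan_insertions(
            segments, consensus_set, repeat_bed, config.scan
        )
        one_end_reads_to_frame(oers).to_csv(
            outdir / f"one_end_reads.{sample.name}.tsv", sep="\t", index=False
        )
        copies_to_frame(copies).to_csv(
            outdir / f"candidate_copies.{sample.name}.tsv", sep="\t", index=False
        )
        summary["samples"][sample.name] = sample_summary
    summary["config"] = config.echo()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
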