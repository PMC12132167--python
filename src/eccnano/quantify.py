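"""Abundance, fold change, coverage tracks and downsampling.

Circle abundance is reported per family as circular reads per
mitochondrial read: the mitochondrial circle is present at comparable copy
number across samples, so dividing by its read count cancels library-size
differences between replicates. Fold changes between conditions are
computed on these normalized values with a small pseudocount and tested by
Welch's unpaired t-test across replicates.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import AlignmentSegment
from .consensus import TransposonConsensus
from .errors import NormalizationError, ParameterError
from .seqio import FastqRead

__all__ = [
    "mito_normalize",
    "fold_change",
    "coverage_track",
    "downsample_reads",
]

ABUNDANCE_COLUMNS = ["sample", "family", "circle_reads", "mito_reads", "normalized"]


def mito_normalize(
    circle_counts: Mapping[str, int], mito_reads: int, sample: str = "sample"
) -> pd.DataFrame:
    """Per-family circular-read counts normalized by mitochondrial reads."""
    if mito_reads <= 0:
        raise NormalizationError(
            f"{sample}: no mitochondrial reads — abundance cannot be normalized"
        )
    rows = [
        (sample, family, int(count), int(mito_reads), count / mito_reads)
        for family, count in sorted(circle_counts.items())
    ]
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def fold_change(
    control: pd.DataFrame,
    treatment: pd.DataFrame,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-family fold change (treatment / control) across replicates.

    Inputs are abundance tables (one row per sample × family, columns as
    produced by :func:`mito_normalize`); families absent from a sample
    count as zero. ``pseudocount`` defaults to the smallest expressible
    normalized unit — one circle read divided by the deepest sample's
    mitochondrial read count — keeping zero-count families finite while
    staying negligible against any family with real signal. The p-value is
    a two-sided Welch (unequal
    variance) unpaired t-test on the normalized replicate values; it is NaN
    with fewer than two replicates per condition.
    """
    for df, label in ((control, "control"), (treatment, "treatment")):
        if df.empty:
            raise ParameterError(f"{label} abundance table is empty")
    families = sorted(set(control["family"]) | set(treatment["family"]))

    def replicate_matrix(df: pd.DataFrame) -> pd.DataFrame:
        wide = df.pivot_table(
            index="family", columns="sample", values="normalized", fill_value=0.0
        )
        return wide.reindex(families, fill_value=0.0)

    ctrl, treat = replicate_matrix(control), replicate_matrix(treatment)
    if pseudocount is None:
        mito = pd.concat([control, treatment]).get("mito_reads")
        if mito is not None and (mito > 0).any():
            pseudocount = 1.0 / float(mito.max())
        else:
            values = np.concatenate([ctrl.to_numpy().ravel(), treat.to_numpy().ravel()])
            nonzero = values[values > 0]
            pseudocount = float(nonzero.min()) if nonzero.size else 1.0

    rows = []
    for family in families:
        c, t = ctrl.loc[family].to_numpy(float), treat.loc[family].to_numpy(float)
        mean_c, mean_t = c.mean(), t.mean()
        fc = (mean_t + pseudocount) / (mean_c + pseudocount)
        if len(c) >= 2 and len(t) >= 2:
            p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
        else:
            p = float("nan")
        rows.append(
            dict(
                family=family,
                mean_control=mean_c,
                mean_treatment=mean_t,
                fold_change=fc,
                log2fc=float(np.log2(fc)),
                p_value=p,
            )
        )
    return pd.DataFrame(rows)


def coverage_track(
    segments: Iterable[AlignmentSegment],
    target: TransposonConsensus | int,
    chrom: str | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-base alignment depth over a target, plus its BedGraph runs.

    depth[i] counts segments whose target interval contains position i.
    BedGraph rows are maximal runs of constant depth (0-based half-open),
    equivalent to a per-base genome-coverage computation.
    """
    if isinstance(target, TransposonConsensus):
        length = target.length
        chrom = chrom or target.name
    else:
        length = int(target)
        chrom = chrom or "target"
    diff = np.zeros(length + 1, dtype=np.int64)
    for seg in segments:
        if seg.target_start >= length:
            continue
        diff[seg.target_start] += 1
        diff[min(seg.target_end, length)] -= 1
    depth = np.cumsum(diff[:-1])
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [length]))
    bedgraph = pd.DataFrame(
        dict(chrom=chrom, start=starts, end=ends, depth=depth[starts])
    )
    return depth, bedgraph


def downsample_reads(
    reads: Sequence[FastqRead], target_bases: int, seed: int = 0
) -> list[FastqRead]:
    """Uniform random downsampling to ~``target_bases`` total bases.

    Reads are selected without replacement in a seeded random order until
    the cumulative base count reaches ``target_bases`` (the last selected
    read may overshoot), then returned in their original order. If the
    input holds fewer bases than requested, all reads are returned with a
    warning.
    """
    if target_bases <= 0:
        raise ParameterError(f"target_bases must be positive, got {target_bases}")
    total = sum(len(r) for r in reads)
    if target_bases >= total:
        if target_bases > total:
            warnings.warn(
                f"requested {target_bases} bases but input holds only {total}; "
                "returning all reads",
                stacklevel=2,
            )
        return list(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    chosen: set[int] = set()
    acc = 0
    for idx in order:
        chosen.add(int(idx))
        acc += len(reads[idx])
        if acc >= target_bases:
            break
    return [r for i, r in enumerate(reads) if i in chosen]
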