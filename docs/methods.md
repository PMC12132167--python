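# Methods

## Circle calling

The unit of inference is the **read chain**: all alignments of one read to
one target, ordered by read coordinate. Reads hitting several transposon
families keep only the family with the largest summed aligned bases
(dominance), so every read votes once; ties break lexicographically for
determinism.

**Circularity** requires ≥2 segments with every consecutive pair adjacent
in *read* coordinates: `read_gap = downstream.read_start −
upstream.read_end ≤ adjacency_tol` (default 100 bp; overlaps, i.e.
negative gaps, always pass). Read-space adjacency — rather than
target-space — is deliberate: rearranged circles jump in target
coordinates at their junction, and target-space adjacency would
misclassify auto-integration junctions. Raising `adjacency_tol` can only
make more chains circular (monotonicity, property-tested).

**Junction deficit.** For consecutive same-strand segments,

    M = (T − upstream.target_end) + downstream.target_start − read_gap

on the forward strand; on the reverse strand the read traverses the
consensus backwards, so the roles of the two target ends swap:
`M = (T − downstream.target_end) + upstream.target_start − read_gap`.
The two LTRs are identical, so the aligner may give a junction's shared
LTR bases to the upstream tail, the downstream head, or both; the algebra
cancels the choice, which the tests assert for all three conventions.
Cross-strand junctions carry no deficit; they are flagged and can never
support a full-length call.

**Decision procedure** (exhaustive and exclusive; every chain receives
exactly one type):

1. chains failing the circularity rule → `not_circular`;
2. chains covering the internal interval `[L, T−L)` to within `cover_tol`
   (default 100 bp) at each end, whose junction deficits vote by strict
   majority `|M − L| ≤ ltr_tol` → `one_ltr_full`, or `|M| ≤ ltr_tol` →
   `two_ltr_full` (`ltr_tol` default 50 bp);
3. otherwise, exactly one LTR fully covered (within `ltr_tol`) →
   `one_ltr_rearranged`;
4. neither LTR covered → `zero_ltr_rearranged`;
5. the remainder — both LTRs covered but junction votes tied, mixed or
   intermediate — → `ambiguous`.

`ambiguous` is an explicit class, excluded from per-type proportions and
tallied separately, rather than silently coerced. Full-internal coverage
is required of the internal interval only, not the LTR extremities: a
1-LTR circle read whose alignments never extend into the 3' LTR region
still qualifies. Multi-monomer chains aggregate junction votes by strict
majority; ties are ambiguous. The estimated monomer count is total aligned
bases divided by the covered-union span; reads spanning <1.2 monomers may
not exhibit a junction at all and are then (correctly) not circular.

The classifier is verified verdict-for-verdict against an independent
rule interpreter on an exhaustive two-segment grid of a miniature
consensus (T=50, L=10, 1 bp steps; read-gap sweep on a 2 bp subgrid), and
round-trips against the generator: 100% type recovery at zero error for
reads with ≥1.2 monomers, ≥90% at 5% substitutions with zero
1-LTR↔2-LTR confusions — both on truth alignments and through minimap2.

## Quantification

Abundance per family = circular reads (any of the four types) /
mitochondrial reads; mitochondrial reads are reads whose dominant target
is the mitochondrial reference. Read counts, not base coverage, keep the
estimator robust to circle size; base-coverage normalisation is a known
alternative this package does not implement. Fold change =
`(mean_treatment + ε) / (mean_control + ε)` with Welch's unequal-variance
two-sided t-test across replicates (NaN below 2+2 replicates). The default
pseudocount ε is the smallest expressible normalized unit — one circle
read divided by the deepest sample's mitochondrial count — which keeps
zero-count families finite yet is negligible for any family with signal;
a pseudocount of the order of a family's own mean would bias large fold
changes downward by up to 2×. Coverage tracks are per-base segment depth
emitted as maximal constant-depth BedGraph runs; Σ(depth × run length)
equals Σ aligned segment lengths by construction and by test.
Downsampling to a base target selects reads without replacement in seeded
random order until the target is reached (last read may overshoot),
mirroring standard long-read downsampling practice.

## One-end-read scan

A qualifying junction needs ≥`end_min` (1,000 bp, inclusive) of transposon
alignment reaching a consensus terminus within `ltr_tol`, immediately
followed on the read (gap ≤ 100 bp) by ≥`flank_min` (200 bp, inclusive)
aligned elsewhere. One record is emitted per qualifying junction, so a
read touching both termini can contribute two. Flank priority: same-family
consensus (potential circle, typed by the same junction-deficit algebra:
M ≈ L → 1-LTR full-length circle read; M ≈ 0 with both termini → 2-LTR;
anything else, including joins into internal sequence and cross-strand
joins, → 1-LTR rearranged circle *or* nested genomic copy, which one-end
evidence cannot distinguish); then genomic; a different-family consensus
flank is unplaceable and discarded as repeat. Genomic flanks are
intersected with the repeat annotation under write-all-overlap (`-wao`)
semantics — one row per overlapping repeat, a null row for none — and the
flank is *unique* when ≥`flank_min` bases fall outside the union of
repeats. The junction site is the genomic coordinate (forward strand,
0-based) of the flank base adjacent to the transposon terminus. Unique
sites cluster per (family, chromosome) by single linkage with
`cluster_window` = 2,000 bp; sites exactly at the window merge (≤), one
base beyond split. Single linkage, not fixed windows, so clustering is
order-invariant and idempotent.

Reference transposon copies legitimately produce one-end reads at their
own edges (their genome alignment spans the junction contiguously); these
appear as candidate copies at reference-copy boundaries and are part of
the expected output, not false positives.

## Synthetic data

The generator emulates the two experiments end to end.

**Circles.** Four mechanistic classes over a consensus built with
byte-identical terminal repeats (defaults: 4,200 bp internal + 2×400 bp
LTR, GC 0.45): 1-LTR full (length T−L), 2-LTR full (T), 1-LTR rearranged
(one LTR + internal truncated at a breakpoint), 0-LTR rearranged
(internal-only fragment). Random breakpoints stay 200 bp clear of
interval ends so the truth class is unambiguous at the caller's
tolerances. A mitochondrial circle (19.5 kb, GC 0.21, fly-like) serves as
the normalisation control. The default simulated mixture
(43.9 / 2.0 / 52.5 / 2.3% across the four classes) mirrors the proportions
reported for the most active element in derepressed fly testes.

**Reads.** Rolling-circle reads are windows of a tandem concatemer:
uniform rotation start, log-normal length with stated arithmetic mean
(default 8 kb, σ=0.6 in log space — conventional nanopore-like values;
run-specific distributions are not modelled), monomer count implied by
length ÷ circle size rather than sampled separately. Reads below
`min_read_length` (default 1 kb) are discarded, emulating removal of
short debranched fragments. Errors are i.i.d. per base (substitution /
insertion / deletion); no homopolymer-aware model — sufficient to stress
the caller's tolerances, not a platform error emulator. Strands are
sampled 50/50. Truth alignments are emitted as exact PAF (segments under
10 bp suppressed, as a real aligner would), read coordinates adjusted for
indels; qualities are constant Q20 placeholders, as no stage consumes
them.

**Genomes.** A random backbone receives full-length reference copies
(optionally one nested inside another's internal region — the geometry
that mimics rearranged-circle junctions in genomic reads) and planted
non-reference copies with a 4 bp target-site duplication (configurable;
a typical LTR-element value). The repeat BED covers every copy plus random
decoy repeats to a configurable fraction of the genome; planted sites are
kept ≥8 kb apart and clear of repeats so junction-spanning reads have
unique flanks. Genomic reads are drawn uniformly from the *sample* genome
(reference + insertions); truth marks junction-spanning reads under the
scan's own thresholds, and the observed spanning count matches the
Lander–Waterman window expectation within binomial noise.

**What the simulations do not capture:** real repeat-family sequence
divergence and mapping ambiguity, chimeric reads, Phi29 branching,
coverage biases, and real breakpoint microhomology. Passing tests
demonstrate the algebra and the pipeline plumbing are correct under the
stated error model; they do not certify performance on real libraries.

## In-silico divergent PCR

Primers are given by their 3'-end coordinate on the reference (forward
extends rightward, reverse leftward) with a configurable footprint length
(default 20 bp). The pair must be outward-facing on the linear reference;
a convergent pair is rejected as ordinary PCR. On a linear template the
result is always `None`; on a circle containing both primer footprints
the product is the exact walked path across the junction,
`(rev_site_end − fwd_site_start) mod circle_size`. Footprints that span a
rearrangement join are treated as absent (no annealing); tests verify
products against a rotation-and-substring brute-force oracle.

## Problem sizes and numerics

Default test and acceptance runs use a 5 kb consensus, 300 kb genomes,
hundreds to a few thousand reads, and 500–1,000 reads per circle type —
sizes chosen so the binomial/Poisson tolerances derived in the tests
(3 SD bands, delta-method t-intervals with 2 df for the 3+3 fold-change
design) are meaningful while the whole suite stays interactive. All
randomness flows through seeded numpy Generators; identical seeds give
byte-identical FASTQ, truth tables and pipeline outputs (summary JSON is
written with sorted keys and no timestamps). Interval formats are
0-based half-open throughout; BED input is validated and required sorted
within chromosome.

## Known limitations

- LTR coordinates are an *input* (FASTA + name→LTR-length annotation);
  the package does not infer LTRs from consensus self-alignment.
- Mitochondrial abundance is read-count based only.
- The scan reports candidate copies from one-end evidence; it does not
  implement a spanning-read non-reference insertion caller, and
  `one_ltr_rearranged_or_nested` is intentionally unresolved.
- The adapter filter counts edits (not strictly substitutions) against
  `max_mismatches`, searching both orientations.
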