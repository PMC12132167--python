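"""Generator contracts: consensus geometry, circle construction, RCA reads,
planted genomes and in-silico divergent PCR."""
import numpy as np
import pandas as pd
import pytest

from eccnano import (
    CircleType,
    build_consensus,
    divergent_pcr,
    make_circle,
    make_mito,
    plant_insertions,
    simulate_gdna_reads,
    simulate_rca_reads,
)
from eccnano.errors import ParameterError
from eccnano.seqio import revcomp


def count_ltr_copies(circle_seq: str, ltr: str) -> int:
    """Exact-match oracle: occurrences of the full LTR in the circle,
    counting across the wrap junction."""
    doubled = circle_seq + circle_seq
    return sum(1 for i in range(len(circle_seq)) if doubled[i : i + len(ltr)] == ltr)


class TestConsensus:
    def test_geometry_and_ltr_identity(self, toy):
        assert toy.length == 5000
        assert toy.sequence[:400] == toy.sequence[4600:]
        assert toy.ltr5 == (0, 400)
        assert toy.ltr3 == (4600, 5000)
        assert toy.internal == (400, 4600)

    def test_deterministic(self):
        a = build_consensus("x", 1000, 100, seed=7)
        b = build_consensus("x", 1000, 100, seed=7)
        assert a.sequence == b.sequence
        assert a.sequence != build_consensus("x", 1000, 100, seed=8).sequence

    @pytest.mark.parametrize("internal,ltr", [(0, 100), (1000, 0), (-5, 100)])
    def test_invalid_lengths_rejected(self, internal, ltr):
        with pytest.raises(ParameterError):
            build_consensus("bad", internal, ltr)


class TestMakeCircle:
    def test_full_length_circle_sizes(self, toy):
        one = make_circle(toy, CircleType.ONE_LTR_FULL)
        two = make_circle(toy, CircleType.TWO_LTR_FULL)
        assert one.size == 4600  # T - L
        assert two.size == 5000  # T
        ltr = toy.sequence[:400]
        assert count_ltr_copies(one.sequence, ltr) == 1
        assert count_ltr_copies(two.sequence, ltr) == 2

    def test_rearranged_circle_contains_one_ltr(self, toy):
        circ = make_circle(toy, CircleType.ONE_LTR_REARRANGED, breakpoint=3000)
        assert circ.size == 3000  # LTR (400) + internal up to 3000
        assert count_ltr_copies(circ.sequence, toy.sequence[:400]) == 1
        zero = make_circle(toy, CircleType.ZERO_LTR_REARRANGED, breakpoint=3000)
        assert count_ltr_copies(zero.sequence, toy.sequence[:400]) == 0

    def test_breakpoint_in_ltr_rejected(self, toy):
        for bad in (100, 4700):
            with pytest.raises(ParameterError):
                make_circle(toy, CircleType.ONE_LTR_REARRANGED, breakpoint=bad)

    def test_every_base_traceable(self, toy):
        for ct in (CircleType.ONE_LTR_FULL, CircleType.ONE_LTR_REARRANGED):
            circ = make_circle(toy, ct, breakpoint=2500)
            rebuilt = "".join(toy.sequence[s:e] for s, e in circ.segments)
            assert rebuilt == circ.sequence


class TestRcaReads:
    def test_zero_error_read_is_tandem_concatemer(self, toy):
        circ = make_circle(toy, CircleType.ONE_LTR_FULL)
        sim = simulate_rca_reads(
            [circ], 20, mean_read_length=3 * circ.size, min_read_length=1000,
            seed=11, length_sigma=0.0,
        )
        tandem = circ.sequence * 4
        for read in sim.reads:
            assert len(read.sequence) == 3 * circ.size
            assert read.sequence in tandem or revcomp(read.sequence) in tandem

    def test_min_read_length_filter(self, toy):
        circ = make_circle(toy, CircleType.ONE_LTR_FULL)
        sim = simulate_rca_reads(
            [circ], 300, mean_read_length=1500, min_read_length=1000, seed=3, length_sigma=0.8
        )
        assert sim.n_discarded > 0
        assert min(len(r.sequence) for r in sim.reads) >= 1000

    def test_mixture_proportions_within_three_binomial_sd(self, toy):
        one = make_circle(toy, CircleType.ONE_LTR_FULL)
        two = make_circle(toy, CircleType.TWO_LTR_FULL)
        n = 4000
        sim = simulate_rca_reads(
            [one, two], n, mean_read_length=2000, min_read_length=500,
            seed=5, weights=[0.7, 0.3], length_sigma=0.3,
        )
        counts = sim.truth["circle_type"].value_counts()
        n_emitted = len(sim.truth)
        for p, ct in ((0.7, "one_ltr_full"), (0.3, "two_ltr_full")):
            sd = np.sqrt(n_emitted * p * (1 - p))
            assert abs(counts.get(ct, 0) - p * n_emitted) <= 3 * sd

    def test_deterministic_and_conserved(self, toy):
        circ = make_circle(toy, CircleType.TWO_LTR_FULL)
        kw = dict(mean_read_length=4000, seed=42, error_rates=(0.02, 0.01, 0.01))
        a = simulate_rca_reads([circ], 50, **kw)
        b = simulate_rca_reads([circ], 50, **kw)
        assert [r.sequence for r in a.reads] == [r.sequence for r in b.reads]
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.alignments == b.alignments
        # conservation: one truth row per emitted read, ids unique
        assert len(a.truth) == len(a.reads)
        assert a.truth["read_id"].is_unique

    def test_parameter_errors(self, toy):
        circ = make_circle(toy, CircleType.ONE_LTR_FULL)
        with pytest.raises(ParameterError):
            simulate_rca_reads([], 10)
        with pytest.raises(ParameterError):
            simulate_rca_reads([circ], 0)
        with pytest.raises(ParameterError):
            simulate_rca_reads([circ], 10, error_rates=(1.5, 0, 0))


class TestPlantedGenome:
    def test_contracts(self, toy):
        g = plant_insertions(200000, toy, n_reference=2, n_planted=0, seed=9)
        assert g.planted_copies == []
        g2 = plant_insertions(300000, toy, n_reference=2, n_planted=2, nested=True, seed=9)
        outer = [c for c in g2.reference_copies if not c.nested]
        inner = [c for c in g2.reference_copies if c.nested]
        assert inner and any(o.start < i.start and i.end < o.end for i in inner for o in outer)
        # repeat BED covers every transposon copy interval
        for copy in g2.reference_copies:
            assert any(
                row.start <= copy.start and copy.end <= row.end
                for row in g2.repeat_bed.itertuples()
            )

    def test_overfull_genome_rejected(self, toy):
        with pytest.raises(ParameterError):
            plant_insertions(20000, toy, n_reference=2, n_planted=3, seed=0)

    def test_sample_sequence_carries_tsd(self, toy):
        g = plant_insertions(150000, toy, n_reference=0, n_planted=1, seed=4, tsd_length=4)
        site = g.planted_copies[0].site
        sample = g.sample_sequence()
        assert len(sample) == g.length + toy.length + 4
        left = sample[site - 10 : site]
        insert = sample[site : site + toy.length]
        after = sample[site + toy.length : site + toy.length + 4]
        assert insert == toy.sequence
        assert after == g.sequence[site - 4 : site]  # duplicated target site
        assert left == g.sequence[site - 10 : site]


class TestGdnaReads:
    def test_truth_flags_consistent_with_read_geometry(self, toy):
        g = plant_insertions(200000, toy, n_reference=1, n_planted=2, seed=13)
        sim = simulate_gdna_reads(g, 400, mean_read_length=6000, length_sigma=0.0, seed=14)
        by_read = {}
        for s in sim.alignments:
            by_read.setdefault(s.read_id, []).append(s)
        flagged = set(sim.truth.loc[sim.truth["insertion_site"].notna(), "read_id"])
        for read_id in flagged:
            segs = by_read[read_id]
            te = [s for s in segs if s.target == "toy"]
            ge = [s for s in segs if s.target == g.chrom]
            assert te and ge, "junction-spanning read must hit both targets"
            assert max(s.target_span for s in te) >= 1000
        # reads aligned only to the transposon never span a genomic junction
        for read_id, segs in by_read.items():
            if all(s.target == "toy" for s in segs):
                assert read_id not in flagged

    def test_junction_spanning_count_matches_lander_waterman(self, toy):
        g = plant_insertions(300000, toy, n_reference=0, n_planted=3, seed=21)
        n_reads, read_len = 800, 4000
        end_min, flank_min = 1000, 200
        sim = simulate_gdna_reads(
            g, n_reads, mean_read_length=read_len, length_sigma=0.0,
            min_read_length=3000, seed=22, end_min=end_min, flank_min=flank_min,
        )
        genome_size = len(g.sample_sequence())
        window = read_len - end_min - flank_min  # start positions spanning one junction
        n_junctions = 2 * len(g.planted_copies)
        expected = n_reads * n_junctions * window / genome_size
        observed = sim.truth["insertion_site"].notna().sum()
        assert abs(observed - expected) <= 3 * np.sqrt(expected)


class TestDivergentPcr:
    def test_linear_template_never_amplifies(self, toy):
        assert divergent_pcr(toy.sequence, fwd_3prime=3000, rev_3prime=1000, reference=toy) is None

    def test_convergent_primers_rejected(self, toy):
        with pytest.raises(ParameterError):
            divergent_pcr(toy.sequence, fwd_3prime=1000, rev_3prime=3000, reference=toy)

    def test_circle_amplifies_with_exact_length(self, toy):
        circ = make_circle(toy, CircleType.ONE_LTR_FULL)
        product = divergent_pcr(circ, fwd_3prime=3000, rev_3prime=1000, reference=toy)
        # walk: fwd 5' at 2981 around the junction to rev site end at 1020
        assert product == (1020 - 2981) % circ.size

    def test_mitochondrial_control_amplifies(self):
        mito = make_mito(seed=3)
        product = divergent_pcr(
            mito, fwd_3prime=12000, rev_3prime=2000, reference=mito.sequence
        )
        assert product == (2020 - 11981) % mito.size

    def test_primer_site_missing_from_rearranged_circle(self, toy):
        circ = make_circle(toy, CircleType.ZERO_LTR_REARRANGED, breakpoint=3000)
        # the circle holds only consensus [3000, 4600); both footprints are absent
        assert divergent_pcr(circ, fwd_3prime=2990, rev_3prime=600, reference=toy) is None
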