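"""One-end-read discovery, repeat intersection, flank classes, clustering."""
import numpy as np
import pandas as pd
import pytest

from eccnano import (
    Fig5dType,
    FlankClass,
    ScanParams,
    classify_flank,
    cluster_copies,
    find_one_end_reads,
    intersect_repeats,
    plant_insertions,
    scan_insertions,
    simulate_gdna_reads,
    type_te_flanked_reads,
)
from eccnano.insertions import OneEndRead

from conftest import seg


@pytest.fixture
def scan_params():
    return ScanParams()


def te_then_flank(te_iv, flank_iv, flank_target="chr1", read_gap=0, te_target="toy"):
    """Read laid out as [transposon segment][flank segment]."""
    te_len = te_iv[1] - te_iv[0]
    fl_len = flank_iv[1] - flank_iv[0]
    a = seg(*te_iv, 0, te_len, read_id="q", target=te_target)
    b = seg(
        *flank_iv, te_len + read_gap, te_len + read_gap + fl_len,
        read_id="q", target=flank_target, target_length=1_000_000,
    )
    return [a, b]


class TestFindOneEndReads:
    def test_qualifying_read_emitted(self, toy, scan_params):
        segs = te_then_flank((3800, 5000), (10_000, 10_300))
        (oer,) = find_one_end_reads(segs, {"toy": toy}, scan_params)
        assert oer.te_end == "3p"
        assert oer.te_aligned == 1200
        assert oer.genomic_site == 10_000

    def test_short_te_span_not_emitted(self, toy, scan_params):
        segs = te_then_flank((4200, 5000), (10_000, 10_300))
        assert find_one_end_reads(segs, {"toy": toy}, scan_params) == []

    def test_te_span_not_reaching_terminus_not_emitted(self, toy, scan_params):
        segs = te_then_flank((3000, 4500), (10_000, 10_300))
        assert find_one_end_reads(segs, {"toy": toy}, scan_params) == []

    def test_exact_thresholds_inclusive(self, toy, scan_params):
        # exactly 1000 bp of transposon end and exactly 200 bp flank qualify
        segs = te_then_flank((4000, 5000), (10_000, 10_200))
        assert len(find_one_end_reads(segs, {"toy": toy}, scan_params)) == 1
        segs = te_then_flank((4001, 5000), (10_000, 10_200))
        assert find_one_end_reads(segs, {"toy": toy}, scan_params) == []
        segs = te_then_flank((4000, 5000), (10_000, 10_199))
        assert find_one_end_reads(segs, {"toy": toy}, scan_params) == []

    def test_same_te_flank_classified_at_discovery(self, toy, scan_params):
        segs = te_then_flank((3800, 5000), (2000, 2400), flank_target="toy")
        (oer,) = find_one_end_reads(segs, {"toy": toy}, scan_params)
        assert oer.flank_class == FlankClass.SAME_TE

    def test_five_prime_end_with_preceding_flank(self, toy, scan_params):
        flank = seg(10_000, 10_300, 0, 300, target="chr1", target_length=1_000_000)
        te = seg(0, 1200, 300, 1500, target="toy")
        (oer,) = find_one_end_reads([flank, te], {"toy": toy}, scan_params)
        assert oer.te_end == "5p"
        assert oer.genomic_site == 10_300


def brute_force_wao(queries, repeats):
    rows = []
    for qc, qs, qe, qn in queries:
        hits = [
            (rc, rs, re, rn)
            for rc, rs, re, rn in repeats
            if rc == qc and max(qs, rs) < min(qe, re)
        ]
        hits.sort(key=lambda h: (h[1], h[2], h[3]))
        if not hits:
            rows.append((qc, qs, qe, qn, ".", -1, -1, ".", 0))
        for rc, rs, re, rn in hits:
            rows.append((qc, qs, qe, qn, rc, rs, re, rn, min(qe, re) - max(qs, rs)))
    return rows


class TestIntersectRepeats:
    def test_simple_overlap(self):
        queries = pd.DataFrame([("chr1", 100, 200, "q1")], columns=["chrom", "start", "end", "name"])
        repeats = pd.DataFrame([("chr1", 150, 250, "rep")], columns=["chrom", "start", "end", "name"])
        out = intersect_repeats(queries, repeats)
        assert len(out) == 1
        assert out.loc[0, "overlap"] == 50

    def test_wao_null_row_for_no_overlap(self):
        queries = pd.DataFrame([("chr1", 0, 50, "q1")], columns=["chrom", "start", "end", "name"])
        repeats = pd.DataFrame([("chr1", 100, 200, "rep")], columns=["chrom", "start", "end", "name"])
        out = intersect_repeats(queries, repeats)
        assert len(out) == 1
        assert out.loc[0, "r_name"] == "."
        assert out.loc[0, "overlap"] == 0

    def test_matches_all_pairs_oracle_on_random_intervals(self):
        rng = np.random.default_rng(17)
        queries = [
            ("chr1" if i % 2 else "chr2", int(s), int(s) + int(l), f"q{i}")
            for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 120), rng.integers(1, 400, 120)))
        ]
        repeats = [
            ("chr1" if i % 3 else "chr2", int(s), int(s) + int(l), f"rep{i}")
            for i, (s, l) in enumerate(zip(rng.integers(0, 5000, 80), rng.integers(1, 500, 80)))
        ]
        qdf = pd.DataFrame(queries, columns=["chrom", "start", "end", "name"])
        rdf = pd.DataFrame(repeats, columns=["chrom", "start", "end", "name"])
        got = [tuple(r) for r in intersect_repeats(qdf, rdf).itertuples(index=False)]
        assert got == brute_force_wao(queries, repeats)


class TestClassifyFlank:
    def _oer(self, flank=(10_000, 10_300)):
        return OneEndRead(
            read_id="q", family="toy", te_end="3p", te_aligned=1500,
            flank_target="chr1", flank_interval=flank, genomic_site=flank[0],
        )

    def test_unique_when_no_repeat_overlap(self, toy, scan_params):
        wao = intersect_repeats(
            pd.DataFrame([("chr1", 10_000, 10_300, "q")], columns=["chrom", "start", "end", "name"]),
            pd.DataFrame([("chr1", 50_000, 51_000, "rep")], columns=["chrom", "start", "end", "name"]),
        )
        assert classify_flank(self._oer(), wao, {"toy": toy}, scan_params) == FlankClass.UNIQUE

    def test_discard_when_fully_repeat(self, toy, scan_params):
        wao = intersect_repeats(
            pd.DataFrame([("chr1", 10_000, 10_300, "q")], columns=["chrom", "start", "end", "name"]),
            pd.DataFrame([("chr1", 9_000, 11_000, "rep")], columns=["chrom", "start", "end", "name"]),
        )
        assert (
            classify_flank(self._oer(), wao, {"toy": toy}, scan_params)
            == FlankClass.REPEAT_DISCARD
        )

    def test_partial_repeat_needs_flank_min_unique(self, toy, scan_params):
        # 300 bp flank, 150 bp in repeat: only 150 unique < 200 -> discard
        wao = intersect_repeats(
            pd.DataFrame([("chr1", 10_000, 10_300, "q")], columns=["chrom", "start", "end", "name"]),
            pd.DataFrame([("chr1", 10_150, 11_000, "rep")], columns=["chrom", "start", "end", "name"]),
        )
        assert (
            classify_flank(self._oer(), wao, {"toy": toy}, scan_params)
            == FlankClass.REPEAT_DISCARD
        )

    def test_same_te_passthrough(self, toy, scan_params):
        oer = OneEndRead(
            read_id="q", family="toy", te_end="3p", te_aligned=1500,
            flank_target="toy", flank_interval=(2000, 2400), flank_class=FlankClass.SAME_TE,
        )
        assert classify_flank(oer, pd.DataFrame(), {"toy": toy}, scan_params) == FlankClass.SAME_TE


class TestTypeTeFlankedReads:
    def _same_te_oer(self, up, down):
        return OneEndRead(
            read_id="q", family="toy", te_end="3p", te_aligned=up.target_span,
            flank_target="toy", flank_interval=(down.target_start, down.target_end),
            flank_class=FlankClass.SAME_TE, upstream=up, downstream=down,
        )

    def test_deficit_equal_ltr_is_one_ltr_circle_read(self, toy, scan_params):
        up = seg(3000, 5000, 0, 2000)
        down = seg(400, 2000, 2000, 3600)  # M = 0 + 400 - 0 = 400 = L
        (typed,) = type_te_flanked_reads([self._same_te_oer(up, down)], toy, scan_params)
        assert typed.fig5d_type == Fig5dType.ONE_LTR_FC

    def test_zero_deficit_both_ends_is_two_ltr_read(self, toy, scan_params):
        up = seg(3000, 5000, 0, 2000)
        down = seg(0, 1600, 2000, 3600)  # M = 0, exits T, enters 0
        (typed,) = type_te_flanked_reads([self._same_te_oer(up, down)], toy, scan_params)
        assert typed.fig5d_type == Fig5dType.TWO_LTR_FC

    def test_internal_join_is_rearranged_or_nested(self, toy, scan_params):
        up = seg(3500, 5000, 0, 1500)
        down = seg(2000, 3000, 1500, 2500)  # flank re-enters internal sequence
        (typed,) = type_te_flanked_reads([self._same_te_oer(up, down)], toy, scan_params)
        assert typed.fig5d_type == Fig5dType.ONE_LTR_REARRANGED_OR_NESTED


def unique_oer(site, read_id, family="toy", chrom="chr1", end="3p"):
    return OneEndRead(
        read_id=read_id, family=family, te_end=end, te_aligned=1500,
        flank_target=chrom, flank_interval=(site, site + 300),
        flank_class=FlankClass.UNIQUE, genomic_site=site,
    )


class TestClusterCopies:
    def test_sites_within_window_merge(self, scan_params):
        copies = cluster_copies([unique_oer(10_000, "a"), unique_oer(11_999, "b")], scan_params)
        assert len(copies) == 1
        assert copies[0].supporting_reads == ("a", "b")

    def test_boundary_exactly_2kb_merges_just_over_splits(self, scan_params):
        assert len(cluster_copies([unique_oer(10_000, "a"), unique_oer(12_000, "b")])) == 1
        assert len(cluster_copies([unique_oer(10_000, "a"), unique_oer(12_001, "b")])) == 2

    def test_empty_and_order_invariant(self, scan_params):
        assert cluster_copies([], scan_params) == []
        oers = [unique_oer(s, f"r{i}") for i, s in enumerate([5000, 30_000, 6500, 31_000])]
        assert cluster_copies(oers) == cluster_copies(list(reversed(oers)))


class TestScanRoundTrip:
    def test_planted_copies_recovered_and_partition_holds(self, toy):
        genome = plant_insertions(250_000, toy, n_reference=1, n_planted=2, seed=31)
        sim = simulate_gdna_reads(genome, 500, mean_read_length=7000, seed=32)
        oers, copies, summary = scan_insertions(
            sim.alignments, genome.consensus_set, genome.repeat_bed
        )
        # partition: every read exactly one flank class; SAME_TE exactly one type
        assert all(o.flank_class is not None for o in oers)
        assert all(
            (o.fig5d_type is not None) == (o.flank_class == FlankClass.SAME_TE) for o in oers
        )
        truth_sites = {p.site for p in genome.planted_copies}
        truth_sites |= {c.start for c in genome.reference_copies if not c.nested}
        truth_sites |= {c.end for c in genome.reference_copies if not c.nested}
        window = 2000
        for site in (p.site for p in genome.planted_copies):
            assert any(
                c.site_window[0] - window <= site <= c.site_window[1] + window for c in copies
            ), f"planted site {site} not recovered"
        for c in copies:
            assert any(
                abs(c.site_window[0] - s) <= window or abs(c.site_window[1] - s) <= window
                for s in truth_sites
            ), f"spurious candidate at {c.site_window}"
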