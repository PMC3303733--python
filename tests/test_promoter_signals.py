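"""Promoter regions, TATA classification, bendability and accessibility."""

import numpy as np
import pytest

from h2hscan.promoter_signals import (
    GenomeTrack,
    PromoterRegion,
    TataBox,
    accessible_segments,
    bendability_track,
    bidirectional_promoter_region,
    classify_accessibility,
    classify_tata,
    genome_mean,
    longest_joint_run,
    read_tata_bed,
    read_track_bedgraph,
    write_tata_bed,
    write_track_bedgraph,
)
from helpers import bruteforce_bendability, bruteforce_segments, gene, pair


def region(start, end, chrom="chrI"):
    return PromoterRegion("gL", "gR", chrom, start, end, "between_cds")


class TestPromoterRegion:
    def genes(self, tss_l=None, tss_r=None):
        right_start = 301 if tss_r is None else max(301, tss_r + 1)
        return {
            "gL": gene("gL", 100, 200, "-", tss=tss_l),
            "gR": gene("gR", right_start, right_start + 99, "+", tss=tss_r),
        }

    def test_between_cds_interval(self):
        r = bidirectional_promoter_region(pair(), self.genes())
        assert (r.start, r.end, r.length) == (201, 300, 100)

    def test_touching_cds_gives_empty_region(self):
        genes = {"gL": gene("gL", 100, 300, "-"), "gR": gene("gR", 301, 400, "+")}
        r = bidirectional_promoter_region(pair(), genes)
        assert r.is_empty and r.length == 0

    def test_between_tss_interval(self):
        r = bidirectional_promoter_region(
            pair(), self.genes(tss_l=500, tss_r=901), source="between_tss"
        )
        assert (r.start, r.end) == (501, 900)

    def test_between_tss_missing_tss_is_error(self):
        with pytest.raises(ValueError, match="TSS"):
            bidirectional_promoter_region(pair(), self.genes(), source="between_tss")

    def test_non_h2h_pair_rejected(self):
        with pytest.raises(ValueError, match="h2h"):
            bidirectional_promoter_region(pair(cls="t2t"), self.genes())


class TestTataClassification:
    @pytest.mark.parametrize(
        "box,expected",
        [
            ((250, 257), "tata_containing"),
            ((301, 308), "tata_less"),
            ((295, 304), "tata_containing"),  # partial overlap counts
            ((195, 201), "tata_containing"),  # one shared base counts
        ],
    )
    def test_interval_intersection(self, box, expected):
        assert classify_tata(region(201, 300), [TataBox("chrI", *box)]) == expected

    def test_other_chromosome_ignored(self):
        assert classify_tata(region(201, 300), [TataBox("chrII", 250, 257)]) == "tata_less"

    def test_adding_boxes_is_monotone(self):
        boxes = [TataBox("chrI", 1, 8)]
        assert classify_tata(region(201, 300), boxes) == "tata_less"
        boxes.append(TataBox("chrI", 250, 257))
        assert classify_tata(region(201, 300), boxes) == "tata_containing"

    def test_empty_region_is_tata_less(self):
        assert classify_tata(region(300, 299), [TataBox("chrI", 1, 1000)]) == "tata_less"


def random_table(rng):
    import itertools

    return {
        "".join(t): float(rng.uniform(-10, 10))
        for t in itertools.product("ACGT", repeat=3)
    }


class TestBendability:
    def test_uniform_sequence_gets_single_triplet_value(self, rng):
        table = random_table(rng)
        out = bendability_track("AAAA", table)
        assert np.allclose(out, table["AAA"])

    def test_length_three_sequence(self, rng):
        table = random_table(rng)
        assert np.allclose(bendability_track("ACG", table), table["ACG"])

    def test_too_short_sequences(self, rng):
        table = random_table(rng)
        assert bendability_track("", table).size == 0
        assert np.isnan(bendability_track("AC", table)).all()

    def test_matches_window_enumeration_oracle(self, rng):
        table = random_table(rng)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            got = bendability_track(seq, table)
            expected = bruteforce_bendability(seq, table)
            assert np.allclose(got, expected, equal_nan=True)

    def test_incomplete_table_rejected(self):
        with pytest.raises(Exception, match="missing"):
            bendability_track("ACGT", {"AAA": 1.0})


class TestGenomeMean:
    def test_constant_track(self):
        assert genome_mean({"c": np.full(10, 3.0)}) == pytest.approx(3.0)

    def test_pooled_not_mean_of_means(self):
        track = {"c1": np.array([1.0, 1.0]), "c2": np.array([3.0])}
        assert genome_mean(track) == pytest.approx(5 / 3)

    def test_nan_bases_excluded(self):
        assert genome_mean({"c": np.array([1.0, np.nan, 3.0])}) == pytest.approx(2.0)

    def test_all_nan_is_error(self):
        with pytest.raises(ValueError):
            genome_mean({"c": np.array([np.nan])})


class TestAccessibleSegments:
    def tracks(self, bend_vals, occ_vals, chrom="chrI"):
        return {chrom: np.asarray(bend_vals, float)}, {chrom: np.asarray(occ_vals, float)}

    def test_fully_accessible_region_is_one_segment(self):
        bend, occ = self.tracks(np.zeros(10), np.zeros(10))
        segs = accessible_segments(region(1, 10), bend, occ, 1.0, 1.0)
        assert segs == [(1, 10)]

    def test_seven_base_run_does_not_qualify(self):
        b = np.ones(20)
        b[5:12] = 0.0  # 7 bases below
        bend, occ = self.tracks(b, np.zeros(20))
        assert accessible_segments(region(1, 20), bend, occ, 0.5, 1.0) == []
        b[5:13] = 0.0  # 8 bases below
        assert accessible_segments(region(1, 20), self.tracks(b, np.zeros(20))[0], occ, 0.5, 1.0) == [(6, 13)]

    def test_strict_inequality_at_threshold(self):
        bend, occ = self.tracks(np.full(10, 1.0), np.zeros(10))
        assert accessible_segments(region(1, 10), bend, occ, 1.0, 1.0) == []

    def test_nan_bases_fail_the_predicate(self):
        b = np.zeros(10)
        b[4] = np.nan  # genomic base 5 becomes a gap, splitting the run
        bend, occ = self.tracks(b, np.zeros(10))
        assert accessible_segments(region(1, 10), bend, occ, 1.0, 1.0, min_len=5) == [(6, 10)]

    def test_region_outside_track_is_error(self):
        bend, occ = self.tracks(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="outside"):
            accessible_segments(region(5, 15), bend, occ, 1.0, 1.0)

    def test_matches_subinterval_enumeration_oracle(self, rng):
        for _ in range(100):
            n = 200
            b = rng.normal(0, 1, n)
            o = rng.normal(0, 1, n)
            mask = (b < 0.0) & (o < 0.0)
            bend, occ = self.tracks(b, o)
            got = accessible_segments(region(1, n), bend, occ, 0.0, 0.0, min_len=8)
            expected = [(s + 1, e + 1) for s, e in bruteforce_segments(mask, 8)]
            assert got == expected

    def test_lowering_min_len_never_removes_segments(self, rng):
        b, o = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        bend, occ = self.tracks(b, o)
        prev = set()
        for ml in (12, 8, 4, 1):
            cur = set(accessible_segments(region(1, 100), bend, occ, 0.0, 0.0, min_len=ml))
            assert prev <= cur
            prev = cur


class TestAccessibilityClass:
    def test_qualifying_run_is_more_accessible(self):
        bend = {"chrI": np.zeros(20)}
        occ = {"chrI": np.zeros(20)}
        assert classify_accessibility(region(1, 20), bend, occ, 1.0, 1.0) == "more_accessible"

    def test_all_above_average_is_less_accessible(self):
        bend = {"chrI": np.ones(20)}
        occ = {"chrI": np.zeros(20)}
        assert classify_accessibility(region(1, 20), bend, occ, 0.5, 1.0) == "less_accessible"

    def test_min_len_longer_than_region(self):
        bend = {"chrI": np.zeros(20)}
        occ = {"chrI": np.zeros(20)}
        assert (
            classify_accessibility(region(1, 5), bend, occ, 1.0, 1.0, min_len=8)
            == "less_accessible"
        )

    def test_empty_region_is_less_accessible(self):
        bend = {"chrI": np.zeros(20)}
        occ = {"chrI": np.zeros(20)}
        assert classify_accessibility(region(5, 4), bend, occ, 1.0, 1.0) == "less_accessible"


class TestTrackIO:
    def test_tata_bed_roundtrip(self, tmp_path):
        boxes = [TataBox("chrI", 251, 258), TataBox("chrII", 1, 8)]
        p = tmp_path / "tata.bed"
        write_tata_bed(boxes, p)
        assert read_tata_bed(p) == boxes

    def test_bedgraph_roundtrip(self, tmp_path, rng):
        data = {"c1": rng.normal(0, 1, 50), "c2": np.full(30, 2.5)}
        track = GenomeTrack("bendability", data)
        p = tmp_path / "t.bedgraph"
        write_track_bedgraph(track, p)
        back = read_track_bedgraph(p, {"c1": 50, "c2": 30}, "bendability")
        for c in data:
            assert np.allclose(back.data[c], data[c])

    def test_uncovered_bases_stay_undefined(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("c1\t0\t5\t1.5\n")
        track = read_track_bedgraph(p, {"c1": 10}, "occupancy")
        assert np.allclose(track.data["c1"][:5], 1.5)
        assert np.isnan(track.data["c1"][5:]).all()
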