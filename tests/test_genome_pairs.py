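"""Pair formation, orientation classification and distance measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from h2hscan.errors import InputFormatError
from h2hscan.genome_pairs import (
    AdjacentPair,
    GeneModel,
    adjacent_pairs,
    bin_distances,
    chromosome_summary,
    classify_pair,
    cr_distance,
    filter_overlapping,
    form_adjacent_pairs,
    read_gene_annotations,
    tss_distance,
)
from helpers import gene


class TestGeneModel:
    def test_rejects_inverted_coordinates(self):
        with pytest.raises(ValueError, match="cds_start"):
            GeneModel("g", "c", "+", 300, 200)

    def test_rejects_unknown_strand(self):
        with pytest.raises(ValueError, match="strand"):
            GeneModel("g", "c", ".", 100, 200)

    @pytest.mark.parametrize("strand,tss", [("+", 150), ("-", 150)])
    def test_rejects_downstream_tss(self, strand, tss):
        with pytest.raises(ValueError, match="TSS"):
            GeneModel("g", "c", strand, 100, 200, tss=tss)


class TestClassification:
    @pytest.mark.parametrize(
        "ls,rs,expected",
        [("-", "+", "h2h"), ("+", "+", "h2t"), ("-", "-", "h2t"), ("+", "-", "t2t")],
    )
    def test_strand_combinations(self, ls, rs, expected):
        assert classify_pair(gene("a", 100, 200, ls), gene("b", 300, 400, rs)) == expected

    @given(st.lists(st.sampled_from("+-"), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strand_flip_swaps_h2h_and_t2t(self, strands):
        """Flipping every strand maps h2h <-> t2t and preserves h2t."""
        genes = [gene(f"g{i}", i * 1000 + 1, i * 1000 + 500, s) for i, s in enumerate(strands)]
        flipped = [
            gene(g.gene_id, g.cds_start, g.cds_end, "+" if g.strand == "-" else "-")
            for g in genes
        ]

        def counts(gs):
            pairs = adjacent_pairs(gs)
            return {c: sum(p.pair_class == c for p in pairs) for c in ("h2h", "h2t", "t2t")}

        c1, c2 = counts(genes), counts(flipped)
        assert c1["h2h"] == c2["t2t"] and c1["t2t"] == c2["h2h"]
        assert c1["h2t"] == c2["h2t"]


class TestDistances:
    @pytest.mark.parametrize(
        "left,right,expected",
        [((100, 200), (301, 400), 100), ((100, 200), (201, 300), 0), ((1, 10), (12, 20), 1)],
    )
    def test_cr_distance_counts_strictly_between(self, left, right, expected):
        a, b = gene("a", *left), gene("b", *right)
        assert cr_distance(a, b) == expected
        # enumeration oracle: bases strictly inside the gap
        assert cr_distance(a, b) == len(range(left[1] + 1, right[0]))

    def test_cr_distance_matches_enumeration_on_random_pairs(self, rng):
        for _ in range(1000):
            s1 = int(rng.integers(1, 5000))
            e1 = s1 + int(rng.integers(0, 500))
            s2 = e1 + 1 + int(rng.integers(0, 300))
            e2 = s2 + int(rng.integers(0, 500))
            a, b = gene("a", s1, e1), gene("b", s2, e2)
            assert cr_distance(a, b) == len([x for x in range(e1 + 1, s2)])

    def test_cr_distance_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            cr_distance(gene("a", 100, 200), gene("b", 150, 300))

    def test_tss_distance_between_divergent_starts(self):
        a = gene("a", 100, 450, "-", tss=500)
        b = gene("b", 950, 1200, "+", tss=901)
        assert tss_distance(a, b) == 400
        assert tss_distance(a, b) == len(range(501, 901))  # enumeration oracle

    def test_tss_distance_adjacent_and_interleaved_floor(self):
        a = gene("a", 100, 450, "-", tss=500)
        b = gene("b", 950, 1200, "+", tss=501)
        assert tss_distance(a, b) == 0
        b_cross = gene("b", 950, 1200, "+", tss=499)
        assert tss_distance(a, b_cross) == 0  # crossing TSSs floored at 0

    def test_tss_distance_missing_tss_is_undefined(self):
        a = gene("a", 100, 450, "-", tss=500)
        b = gene("b", 950, 1200, "+")
        assert tss_distance(a, b) is None

    def test_tss_distance_requires_h2h(self):
        with pytest.raises(ValueError, match="h2h"):
            tss_distance(gene("a", 100, 200, "+"), gene("b", 300, 400, "+"))


class TestPairFormation:
    def test_n_minus_one_pairs_per_chromosome(self):
        genes = [gene(f"g{i}", i * 100 + 1, i * 100 + 50) for i in range(3)]
        assert len(form_adjacent_pairs(genes)) == 2
        assert len(form_adjacent_pairs(genes[:1])) == 0

    def test_order_invariance(self, rng):
        genes = [gene(f"g{i}", i * 100 + 1, i * 100 + 50, chrom=f"c{i % 3}") for i in range(30)]
        baseline = adjacent_pairs(genes)
        for _ in range(5):
            shuffled = [genes[i] for i in rng.permutation(len(genes))]
            assert adjacent_pairs(shuffled) == baseline

    @pytest.mark.parametrize(
        "right,kept",
        [((150, 300), False), ((201, 300), True), ((200, 300), False)],
    )
    def test_overlap_filter_uses_closed_intervals(self, right, kept):
        cand = [(gene("a", 100, 200), gene("b", *right))]
        assert bool(filter_overlapping(cand)) is kept

    def test_touching_pair_has_zero_cr_distance(self):
        pairs = adjacent_pairs([gene("a", 100, 200, "-"), gene("b", 201, 300, "+")])
        assert pairs[0].cr_distance == 0 and pairs[0].pair_class == "h2h"

    def test_partition_into_three_classes(self, small_synth):
        pairs = small_synth.pairs
        total = sum(sum(p.pair_class == c for p in pairs) for c in ("h2h", "h2t", "t2t"))
        assert total == len(pairs)


class TestReaders:
    def test_tsv_roundtrip_fields(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("gA chrI + 100 200\ngB chrI - 300 400\n")
        genes = read_gene_annotations(f, fmt="tsv")
        assert genes[0] == GeneModel("gA", "chrI", "+", 100, 200)
        assert genes[1].strand == "-" and genes[1].tss is None

    def test_tsv_unknown_strand_is_hard_error(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("gA chrI . 100 200\n")
        with pytest.raises(InputFormatError, match="gA"):
            read_gene_annotations(f, fmt="tsv")

    def test_tsv_inverted_coordinates_skipped_with_warning(self, tmp_path, caplog):
        f = tmp_path / "genes.tsv"
        f.write_text("gA chrI + 300 200\ngB chrI + 400 500\n")
        with caplog.at_level("WARNING"):
            genes = read_gene_annotations(f, fmt="tsv")
        assert [g.gene_id for g in genes] == ["gB"]
        assert any("gA" in r.message for r in caplog.records)

    def test_gff3_reader(self, tmp_path):
        f = tmp_path / "genes.gff3"
        f.write_text(
            "##gff-version 3\n"
            "chrI\tsrc\tgene\t100\t200\t.\t+\t.\tID=gA\n"
            "chrI\tsrc\tgene\t300\t400\t.\t-\t.\tID=gB\n"
        )
        genes = read_gene_annotations(f, fmt="gff3")
        assert [g.gene_id for g in genes] == ["gA", "gB"]

    def test_gff3_dot_strand_is_hard_error(self, tmp_path):
        f = tmp_path / "genes.gff3"
        f.write_text("##gff-version 3\nchrI\tsrc\tgene\t100\t200\t.\t.\t.\tID=gA\n")
        with pytest.raises(InputFormatError, match="gA"):
            read_gene_annotations(f, fmt="gff3")


class TestChromosomeSummary:
    def test_density_and_percentages(self):
        # arithmetic of a published-style row: 117 genes on a 230,208 bp
        # chromosome -> 5.08 genes/10kbp; 26 h2h of 98 pairs -> 26.5%
        genes = [gene(f"g{i}", i * 100 + 1, i * 100 + 50, chrom="c1") for i in range(117)]
        pairs = (
            [AdjacentPair(f"a{i}", f"b{i}", "c1", "h2h", 10) for i in range(26)]
            + [AdjacentPair(f"c{i}", f"d{i}", "c1", "h2t", 10) for i in range(41)]
            + [AdjacentPair(f"e{i}", f"f{i}", "c1", "t2t", 10) for i in range(31)]
        )
        df = chromosome_summary(genes, pairs, {"c1": 230_208})
        row = df[df.chrom == "c1"].iloc[0]
        assert round(row.density, 2) == 5.08
        assert row.n_pairs == 98
        assert round(row.pct_h2h, 1) == 26.5

    def test_missing_chromosome_length_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            chromosome_summary([gene("g", 1, 10, chrom="cX")], [], {"cY": 1000})

    def test_zero_pair_chromosome_reports_nan_percentages(self):
        df = chromosome_summary([gene("g", 1, 10, chrom="c1")], [], {"c1": 1000})
        assert np.isnan(df.iloc[0].pct_h2h)

    def test_overall_row_pools_chromosomes(self):
        genes = [gene("g1", 1, 10, chrom="c1"), gene("g2", 1, 10, chrom="c2")]
        df = chromosome_summary(genes, [], {"c1": 10_000, "c2": 10_000})
        overall = df[df.chrom == "overall"].iloc[0]
        assert overall.n_genes == 2 and overall.density == 1.0


class TestDistanceHistogram:
    def test_half_open_bin_boundaries(self):
        h = bin_distances([0, 199, 200])
        assert h.fractions[0] == pytest.approx(2 / 3)
        assert h.fractions[1] == pytest.approx(1 / 3)

    def test_empty_input_gives_zero_histogram(self):
        h = bin_distances([])
        assert h.n_total == 0 and not h.fractions.any()

    def test_overflow_counts_in_denominator_only(self):
        h = bin_distances([3500, 100])
        assert h.n_overflow == 1
        assert h.fractions[0] == pytest.approx(0.5)
        assert h.fractions.sum() == pytest.approx(0.5)

    def test_negative_value_is_hard_error(self):
        with pytest.raises(ValueError, match="negative"):
            bin_distances([-1])
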