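"""Promoter/enhancer classification and closest-TSS assignment."""

import pytest

from cremap.annotation import (
    ENHANCER,
    PROMOTER,
    GeneModel,
    classify_peak,
    classify_peaks,
    closest_tss,
    promoter_window,
    read_gene_model,
    read_gene_model_gtf,
)
from cremap.intervals import GenomicInterval
from cremap.peaks import MergedPeak

from conftest import oracle_closest_tss, random_intervals


def gm(gene, chrom, strand, tss):
    return GeneModel(gene, chrom, strand, tss)


def mp(chrom, start, end, mid="m1"):
    return MergedPeak(mid, GenomicInterval(chrom, start, end), {"ds": (mid,)})


class TestPromoterWindow:
    def test_closed_pm2kb_rendered_half_open(self):
        w = promoter_window(gm("G", "chr1", "+", 5000), 2000)
        assert (w.start, w.end) == (3000, 7001)

    def test_clipped_at_origin(self):
        w = promoter_window(gm("G", "chr1", "+", 1000), 2000)
        assert (w.start, w.end) == (0, 3001)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            promoter_window(gm("G", "chr1", "+", 5000), 0)

    @pytest.mark.parametrize("tss,w", [(5000, 2000), (123, 7), (10, 3), (999, 500)])
    def test_membership_equals_distance_rule_base_by_base(self, tss, w):
        win = promoter_window(gm("G", "chr1", "+", tss), w)
        lo = max(0, tss - w - 2)
        for base in range(lo, tss + w + 3):
            inside = win.start <= base < win.end
            assert inside == (abs(base - tss) <= w)


class TestClosestTss:
    def test_midpoint_exactly_at_tss(self):
        genes = [gm("G1", "chr1", "+", 104), gm("G2", "chr1", "+", 9000)]
        gene, d = closest_tss(mp("chr1", 100, 109), genes)  # midpoint 104
        assert (gene, d) == ("G1", 0)

    def test_tie_breaks_to_smallest_symbol(self):
        genes = [gm("XYZ", "chr1", "+", 90), gm("ABC", "chr1", "+", 110)]
        gene, d = closest_tss(mp("chr1", 98, 103), genes)  # midpoint 100
        assert gene == "ABC"
        assert abs(d) == 10

    def test_no_gene_on_chromosome(self):
        assert closest_tss(mp("chr9", 0, 10), [gm("G", "chr1", "+", 5)]) == (None, None)

    def test_distance_sign_strand_aware(self):
        # peak midpoint 100, TSS 500: upstream of a + gene, downstream of a - gene
        plus = [gm("P", "chr1", "+", 500)]
        minus = [gm("M", "chr1", "-", 500)]
        assert closest_tss(mp("chr1", 96, 105), plus)[1] == -400
        assert closest_tss(mp("chr1", 96, 105), minus)[1] == 400

    def test_matches_linear_scan_oracle(self, rng):
        genes = [
            GeneModel(
                f"g{i:03d}",
                f"chr{int(rng.integers(1, 4))}",
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(0, 100_000)),
            )
            for i in range(200)
        ]
        tuples = [(g.gene, g.chrom, g.strand, g.tss) for g in genes]
        for iv in random_intervals(rng, 1000, max_pos=100_000):
            expected = oracle_closest_tss(iv.midpoint, iv.chrom, tuples)
            assert closest_tss(iv, genes) == expected


class TestClassify:
    GENES = [gm("G1", "chr1", "+", 5000), gm("G2", "chr1", "-", 50_000)]

    def test_peak_spanning_tss_is_promoter(self):
        a = classify_peak(mp("chr1", 4900, 5100), self.GENES)
        assert a.klass == PROMOTER
        assert a.gene == "G1"
        assert abs(a.distance) <= 1

    def test_no_genes_on_chromosome_gives_enhancer_none(self):
        a = classify_peak(mp("chrX", 100, 200), self.GENES)
        assert (a.gene, a.distance, a.klass) == (None, None, ENHANCER)

    def test_enhancer_still_reports_closest_gene(self):
        a = classify_peak(mp("chr1", 20_000, 20_500), self.GENES)
        assert a.klass == ENHANCER
        assert a.gene == "G1"

    @pytest.mark.parametrize("offset", range(1995, 2006))
    def test_boundary_sweep_half_open_window(self, offset):
        # window covers bases 3000..7000 inclusive; a width-100 peak
        # starting at tss+offset overlaps iff its start <= tss+2000
        peak = mp("chr1", 5000 + offset, 5000 + offset + 100)
        a = classify_peak(peak, self.GENES)
        assert a.klass == (PROMOTER if offset <= 2000 else ENHANCER)

    def test_monotone_in_window_width(self, rng):
        for iv in random_intervals(rng, 200, chroms=("chr1",), max_pos=60_000):
            calls = [
                classify_peak(iv, self.GENES, w=w).klass for w in (500, 2000, 8000)
            ]
            assert calls == sorted(calls)  # promoter calls never flip back

    def test_peak_containing_tss_is_promoter_for_any_width(self):
        peak = mp("chr1", 4000, 6000)
        for w in (1, 10, 2000):
            assert classify_peak(peak, self.GENES, w=w).klass == PROMOTER

    def test_midpoint_mode_is_stricter(self):
        # peak touches the window edge but its midpoint is far outside
        peak = mp("chr1", 6900, 9000)
        assert classify_peak(peak, self.GENES).klass == PROMOTER
        assert (
            classify_peak(peak, self.GENES, proximity_mode="midpoint").klass
            == ENHANCER
        )

    def test_batch_matches_single(self, rng):
        peaks = [
            MergedPeak(f"m{i}", iv, {"ds": (f"m{i}",)})
            for i, iv in enumerate(random_intervals(rng, 100, chroms=("chr1",), max_pos=60_000))
        ]
        batch = classify_peaks(peaks, self.GENES)
        for p in peaks:
            assert batch[p.merged_id] == classify_peak(p, self.GENES)


class TestGeneModelReaders:
    def test_tsv_reader(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text("gene\tchrom\tstrand\ttss\nG1\tchr1\t+\t1000\nG2\tchr2\t-\t5000\n")
        genes = read_gene_model(f)
        assert [(g.gene, g.chrom, g.strand, g.tss) for g in genes] == [
            ("G1", "chr1", "+", 1000),
            ("G2", "chr2", "-", 5000),
        ]

    def test_tsv_duplicate_record_rejected(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text(
            "gene\tchrom\tstrand\ttss\nG1\tchr1\t+\t1000\nG1\tchr1\t+\t1000\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_gene_model(f)

    def test_multi_tss_gene_gets_suffixed_records(self, tmp_path):
        f = tmp_path / "genes.tsv"
        f.write_text(
            "gene\tchrom\tstrand\ttss\nG1\tchr1\t+\t1000\nG1\tchr1\t+\t9000\n"
        )
        genes = read_gene_model(f)
        assert [g.record_id for g in genes] == ["G1", "G1#2"]
        assert {g.gene for g in genes} == {"G1"}
        # classification uses all TSSs but reports the base symbol
        a = classify_peak(mp("chr1", 8950, 9050), genes)
        assert (a.gene, a.klass) == ("G1", PROMOTER)

    def test_gtf_reader_converts_coordinates_and_strand(self, tmp_path):
        f = tmp_path / "genes.gtf"
        f.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1"; gene_name "G1";\n'
            'chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "g2"; gene_name "G2";\n'
            'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "g1";\n'
        )
        genes = read_gene_model_gtf(f)
        # + strand: TSS = 1-based start converted to 0-based; - strand: end-1
        assert [(g.gene, g.tss) for g in genes] == [("G1", 1000), ("G2", 5999)]
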