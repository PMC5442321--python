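"""Interactome table: assembly, serialization round-trip, gene-set query."""

import pytest

from cremap.annotation import ENHANCER, PROMOTER, TssAssignment
from cremap.intervals import GenomicInterval
from cremap.linking import EnhancerAssignment
from cremap.peaks import MergedPeak
from cremap.table import (
    NOT_APPLICABLE,
    AnnotationRecord,
    TableBuildError,
    TableParseError,
    available_channels,
    build_table,
    query_geneset,
    read_table,
    write_table,
)

from conftest import oracle_query, random_records


def mp(mid, chrom, start, end, prov=None):
    return MergedPeak(mid, GenomicInterval(chrom, start, end), prov or {"ds": (mid,)})


class TestBuildTable:
    def test_promoter_and_enhancer_rows(self):
        peaks = [mp("p1", "chr1", 100, 200), mp("p2", "chr1", 5000, 5200)]
        tss = {
            "p1": TssAssignment("G1", 10, PROMOTER),
            "p2": TssAssignment("G1", 4900, ENHANCER),
        }
        links = [EnhancerAssignment("p2", {"hic": ("G2",)})]
        records = build_table(peaks, tss, links, ["hic"])
        assert [r.merged_id for r in records] == ["p1", "p2"]
        assert records[0].links["hic"] is NOT_APPLICABLE
        assert records[1].links["hic"] == ("G2",)

    def test_unlinked_enhancer_gets_na_in_every_set(self):
        peaks = [mp("p1", "chr1", 100, 200)]
        tss = {"p1": TssAssignment("G1", 9000, ENHANCER)}
        links = [EnhancerAssignment("p1", {"hic": None, "chic": None})]
        (r,) = build_table(peaks, tss, links, ["hic", "chic"])
        assert r.links == {"hic": None, "chic": None}

    def test_id_mismatch_rejected_with_symmetric_difference(self):
        peaks = [mp("p1", "chr1", 100, 200)]
        with pytest.raises(TableBuildError, match="p2"):
            build_table(peaks, {"p2": TssAssignment("G1", 0, PROMOTER)}, [], [])
        tss = {"p1": TssAssignment("G1", 9000, ENHANCER)}
        with pytest.raises(TableBuildError, match="p9"):
            build_table(
                peaks, tss, [EnhancerAssignment("p9", {"hic": None})], ["hic"]
            )

    def test_conservation_row_per_peak(self, rng):
        records = random_records(rng, n=500)
        peaks = [
            MergedPeak(r.merged_id, r.interval, r.provenance) for r in records
        ]
        tss = {
            r.merged_id: TssAssignment(r.closest_gene, r.distance, r.klass)
            for r in records
        }
        links = [
            EnhancerAssignment(r.merged_id, dict(r.links))
            for r in records
            if r.klass == ENHANCER
        ]
        out = build_table(peaks, tss, links, ["hic", "chic"])
        assert len(out) == len(peaks)
        assert sorted(r.merged_id for r in out) == sorted(p.merged_id for p in peaks)


class TestRecordInvariants:
    def test_promoter_rows_must_use_sentinel(self):
        with pytest.raises(ValueError, match="not-applicable"):
            AnnotationRecord(
                "p1", GenomicInterval("chr1", 0, 10), {"ds": ("x",)},
                "G1", 5, PROMOTER, {"hic": ("G2",)},
            )

    def test_enhancer_rows_reject_sentinel_and_empty_tuple(self):
        with pytest.raises(ValueError):
            AnnotationRecord(
                "p1", GenomicInterval("chr1", 0, 10), {"ds": ("x",)},
                "G1", 5, ENHANCER, {"hic": NOT_APPLICABLE},
            )
        with pytest.raises(ValueError, match="empty"):
            AnnotationRecord(
                "p1", GenomicInterval("chr1", 0, 10), {"ds": ("x",)},
                "G1", 5, ENHANCER, {"hic": ()},
            )


class TestRoundTrip:
    def test_empty_table(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_table([], path)
        assert read_table(path) == []

    def test_na_token_appears_literally(self, tmp_path, rng):
        records = random_records(rng, n=30)
        path = tmp_path / "t.tsv"
        write_table(records, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        na_cells = sum(l.split("\t").count("NA") for l in body[1:])
        assert na_cells > 0

    def test_identity_and_byte_stability(self, tmp_path, rng):
        for trial in range(20):
            records = random_records(rng)
            p1, p2 = tmp_path / f"a{trial}.tsv", tmp_path / f"b{trial}.tsv"
            write_table(records, p1)
            back = read_table(p1)
            assert back == records
            write_table(back, p2)
            assert p1.read_bytes() == p2.read_bytes()

    def test_strict_compat_collapses_dot_to_na(self, tmp_path, rng):
        records = [r for r in random_records(rng, n=30) if r.klass == PROMOTER]
        path = tmp_path / "t.tsv"
        write_table(records, path, strict_compat=True)
        text = path.read_text()
        assert "\t.\t" not in text and not text.rstrip().endswith("\t.")
        # promoter-row NA reads back as the not-applicable sentinel
        back = read_table(path)
        for r in back:
            assert all(v is NOT_APPLICABLE for v in r.links.values())

    @pytest.mark.parametrize(
        "mutation,match",
        [
            (lambda l: l.replace("\t1\t", "\t7\t", 1), "klass"),
            (lambda l: l + "\textra", "fields"),
        ],
    )
    def test_malformed_rows_report_line_numbers(self, tmp_path, rng, mutation, match):
        records = random_records(rng, n=5)
        records = [r for r in records if r.klass == PROMOTER][:1]
        if not records:
            pytest.skip("no promoter row drawn")
        path = tmp_path / "t.tsv"
        write_table(records, path)
        lines = path.read_text().splitlines()
        lines[-1] = mutation(lines[-1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TableParseError, match=match):
            read_table(path)


class TestQuery:
    def _table(self):
        return [
            AnnotationRecord(
                "p1", GenomicInterval("chr1", 100, 200), {"ds": ("a",)},
                "G1", 5, PROMOTER, {"hic": NOT_APPLICABLE},
            ),
            AnnotationRecord(
                "p2", GenomicInterval("chr1", 5000, 5100), {"ds": ("b",)},
                "G9", 4000, ENHANCER, {"hic": ("G1", "G2")},
            ),
            AnnotationRecord(
                "p3", GenomicInterval("chr1", 9000, 9100), {"ds": ("c",)},
                "G9", 8000, ENHANCER, {"hic": ("G1",)},
            ),
            AnnotationRecord(
                "p4", GenomicInterval("chr2", 100, 200), {"ds": ("d",)},
                "G1", 20, ENHANCER, {"hic": None},
            ),
        ]

    def test_all_channels_counts_distinct_records(self):
        res = query_geneset(self._table(), ["G1"])
        assert {r.merged_id for r in res.records} == {"p1", "p2", "p3"}
        assert res.gene_counts == {"G1": 3}

    def test_enhancer_closest_gene_is_not_an_assignment(self):
        # p4's closest gene is G1 but it is an enhancer with no loop:
        # the closest-promoter channel must not match it
        res = query_geneset(self._table(), ["G1"], ["closest-promoter"])
        assert {r.merged_id for r in res.records} == {"p1"}

    def test_channel_restriction(self):
        res = query_geneset(self._table(), ["G1"], ["interaction:hic"])
        assert {r.merged_id for r in res.records} == {"p2", "p3"}

    def test_absent_symbol_gives_empty_result(self):
        res = query_geneset(self._table(), ["NOPE"])
        assert res.records == [] and res.gene_counts == {}

    def test_case_sensitivity_and_fold_case(self):
        assert query_geneset(self._table(), ["g1"]).records == []
        res = query_geneset(self._table(), ["g1"], fold_case=True)
        assert {r.merged_id for r in res.records} == {"p1", "p2", "p3"}

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            query_geneset(self._table(), [])

    def test_matches_row_scan_oracle(self, rng):
        genes = [f"G{i}" for i in range(1, 30)]
        for _ in range(50):
            records = random_records(rng)
            geneset = [str(g) for g in rng.choice(genes, size=int(rng.integers(1, 6)))]
            channels = list(available_channels(records or random_records(rng, n=1)))
            k = int(rng.integers(1, len(channels) + 1))
            chosen = [channels[int(i)] for i in rng.choice(len(channels), size=k, replace=False)]
            res = query_geneset(records, geneset, chosen)
            assert sorted(r.merged_id for r in res.records) == sorted(
                oracle_query(records, geneset, chosen)
            )

    def test_query_all_genes_returns_records_with_any_assignment(self, rng):
        records = random_records(rng, n=40)
        all_genes = {r.closest_gene for r in records if r.closest_gene} | {
            g
            for r in records
            for cell in r.links.values()
            if isinstance(cell, tuple)
            for g in cell
        }
        res = query_geneset(records, sorted(all_genes))
        expected = {
            r.merged_id
            for r in records
            if (r.klass == PROMOTER and r.closest_gene)
            or any(isinstance(c, tuple) for c in r.links.values())
        }
        assert {r.merged_id for r in res.records} == expected
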