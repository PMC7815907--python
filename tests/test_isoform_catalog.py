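import numpy as np
import pandas as pd
import pytest

from isodie.annotation_io import TranscriptModel, load_annotation
from isodie.isoform_catalog import (
    REJECT_ANNOTATED_TRUNCATION,
    REJECT_INTRON_SUPPORT,
    REJECT_NOVEL_TRUNCATION,
    UsageTable,
    assign_to_annotated,
    build_usage_tables,
    collapse_top_k,
    discover_novel,
    is_subchain,
    load_junction_support,
    write_enhanced_annotation,
)
from isodie.read_processing import AlignedLongRead, Csmm


def make_csmm(gene, introns, start, end, cell_type="EN", sample="HIPP",
              tss="T1", pa="P1", rid="r", strand="+"):
    read = AlignedLongRead(rid, "chr1", strand, start, end, tuple(introns))
    return Csmm(read, (gene,), tss, pa, cell_type, strand)


class TestUsageTable:
    def test_pi_is_within_group_fraction(self):
        csmms = [
            make_csmm("g", [(200, 300)], 100, 500, rid=f"x{i}") for i in range(10)
        ] + [make_csmm("g", [(250, 300)], 100, 500, rid=f"y{i}") for i in range(5)]
        tables = build_usage_tables(csmms, lambda c: c.cell_type)
        t = tables["g"]
        pi = t.pi("EN").sort_values(ascending=False)
        assert pi.tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_empty_group_pi_is_undefined(self):
        t = UsageTable.from_counts("g", {"a": {"EN": 5, "IN": 0}, "b": {"EN": 5, "IN": 0}})
        assert t.pi("IN") is None

    def test_rank_ties_break_by_string_order(self):
        t = UsageTable.from_counts(
            "g", {"X": {"A": 7}, "Y": {"A": 7}, "Z": {"A": 3}}
        )
        ranks = t.ranks()
        assert ranks["X"] == 1 and ranks["Y"] == 2 and ranks["Z"] == 3


class TestCollapse:
    def test_twelve_isoforms_collapse_to_eleven_rows(self):
        counts = {f"i{chr(97 + k)}": {"A": 20 - k, "B": k + 1} for k in range(12)}
        t = UsageTable.from_counts("g", counts)
        mat, labels = collapse_top_k(t, ("A", "B"), k=10)
        assert mat.shape == (11, 2)
        assert labels[-1] == "<other>"
        # conservation of per-group totals
        assert mat.sum(axis=0).tolist() == [
            t.group_total("A"), t.group_total("B")
        ]

    def test_few_isoforms_no_collapse_row(self):
        t = UsageTable.from_counts(
            "g", {"a": {"A": 5, "B": 1}, "b": {"A": 2, "B": 2}, "c": {"A": 1, "B": 5}}
        )
        mat, labels = collapse_top_k(t, ("A", "B"), k=10)
        assert mat.shape == (3, 2)
        assert "<other>" not in labels


class TestAssignToAnnotated:
    def _tx(self, tid, start, end):
        return TranscriptModel(tid, "g", "chr1", "+", ((start, 500), (700, end)))

    def test_minimal_end_divergence_wins(self):
        read = make_csmm("g", [(500, 700)], 100, 2000)
        a = self._tx("A", 90, 2010)   # sum 20
        b = self._tx("B", 150, 2000)  # sum 50
        assert assign_to_annotated(read, [a, b]) == "A"

    def test_tie_falls_back_to_tss_divergence(self):
        read = make_csmm("g", [(500, 700)], 100, 2000)
        a = self._tx("A", 130, 2000)  # sum 30, TSS diff 30
        b = self._tx("B", 100, 2030)  # sum 30, TSS diff 0
        assert assign_to_annotated(read, [a, b]) == "B"

    def test_residual_tie_smallest_id(self):
        read = make_csmm("g", [(500, 700)], 100, 2000)
        a = self._tx("tB", 100, 2000)
        b = self._tx("tA", 100, 2000)
        assert assign_to_annotated(read, [a, b]) == "tA"

    def test_empty_candidates_is_novel(self):
        assert assign_to_annotated(make_csmm("g", [(1, 2)], 0, 10), []) is None


class TestSubchain:
    @pytest.mark.parametrize(
        "sub, full, expected",
        [
            (((1, 2),), ((1, 2), (3, 4)), True),
            (((3, 4),), ((1, 2), (3, 4)), True),
            (((1, 2), (3, 4)), ((1, 2), (3, 4)), True),
            (((1, 2), (5, 6)), ((1, 2), (3, 4), (5, 6)), False),  # not contiguous
            ((), ((1, 2),), False),
            (((1, 2), (3, 4)), ((1, 2),), False),
        ],
    )
    def test_contiguity(self, sub, full, expected):
        assert is_subchain(sub, full) == expected


class TestDiscoverNovel:
    """Hand-built rule scenarios; full planted recovery is exercised on the
    simulated study in test_acceptance."""

    def _annot(self, tmp_path):
        lines = [
            'chr1\tx\tgene\t1\t1000\t.\t+\t.\tgene_id "g";',
            'chr1\tx\ttranscript\t1\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
            'chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
            'chr1\tx\texon\t401\t500\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
            'chr1\tx\texon\t601\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
        ]
        p = tmp_path / "a.gtf"
        p.write_text("\n".join(lines) + "\n")
        return load_annotation(p)

    def _support(self, tmp_path, rows):
        p = tmp_path / "sj.tsv"
        df = pd.DataFrame(rows, columns=["chrom", "intron_start", "intron_end", "strand", "unique_count"])
        df.to_csv(p, sep="\t", index=False)
        return load_junction_support(p)

    def test_truncation_of_annotated_rejected(self, tmp_path):
        genes = self._annot(tmp_path)
        sr = self._support(tmp_path, [("chr1", 300, 400, "+", 9), ("chr1", 500, 600, "+", 9)])
        # chain = last two introns of t1 -> contiguous subsequence
        c = make_csmm("g", [(300, 400), (500, 600)], 250, 1000)
        (res,) = discover_novel([c], genes, sr)
        assert not res.accepted and res.rejection_rule == REJECT_ANNOTATED_TRUNCATION

    def test_low_intron_support_rejected(self, tmp_path):
        genes = self._annot(tmp_path)
        sr = self._support(tmp_path, [("chr1", 100, 600, "+", 1)])
        c = make_csmm("g", [(100, 600)], 0, 1000)  # novel merged intron, support 1
        (res,) = discover_novel([c], genes, sr)
        assert not res.accepted and res.rejection_rule == REJECT_INTRON_SUPPORT

    def test_novel_truncation_keeps_longest(self, tmp_path):
        genes = self._annot(tmp_path)
        sr = self._support(
            tmp_path,
            [("chr1", 100, 200, "+", 9), ("chr1", 300, 600, "+", 9)],
        )
        long = make_csmm("g", [(100, 200), (300, 600)], 0, 1000, rid="L")
        short = make_csmm("g", [(300, 600)], 250, 1000, rid="S")
        res = {r.n_reads and tuple(r.chain): r for r in discover_novel([long, short], genes, sr)}
        accepted = [r for r in res.values() if r.accepted]
        rejected = [r for r in res.values() if not r.accepted]
        assert len(accepted) == 1 and accepted[0].chain == ((100, 200), (300, 600))
        assert rejected[0].rejection_rule == REJECT_NOVEL_TRUNCATION


class TestEnhancedAnnotation:
    def test_round_trip_reproduces_novel_chain(self, tmp_path):
        lines = [
            'chr1\tx\tgene\t1\t1000\t.\t+\t.\tgene_id "g";',
            'chr1\tx\ttranscript\t1\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
            'chr1\tx\texon\t601\t1000\t.\t+\t.\tgene_id "g"; transcript_id "t1";',
        ]
        p = tmp_path / "a.gtf"
        p.write_text("\n".join(lines) + "\n")
        genes = load_annotation(p)

        from isodie.isoform_catalog import NovelIsoform

        iso = NovelIsoform(
            gene_id="g", chain=((100, 300), (400, 600)), n_reads=5,
            start=0, end=1000, strand="+", chrom="chr1",
            tss_peak_id="T", polya_peak_id="P", accepted=True,
        )
        counts = pd.DataFrame({"HIPP_EN": [5]}, index=["g|T|100-300;400-600|P"])
        out_gtf = tmp_path / "enhanced.gtf"
        out_tsv = tmp_path / "counts.tsv"
        novel_tx = write_enhanced_annotation([iso], genes, counts, out_gtf, out_tsv)
        assert [t.transcript_id for t in novel_tx] == ["g.novel1"]

        reloaded = load_annotation(out_gtf)
        assert reloaded.transcripts["g.novel1"].intron_chain == ((100, 300), (400, 600))
        assert "isodie_novel" in out_gtf.read_text()
        written = pd.read_table(out_tsv, index_col="isoform")
        assert written.loc["g|T|100-300;400-600|P", "HIPP_EN"] == 5

    def test_no_accepted_isoforms_leaves_annotation_equivalent(self, tmp_path, tiny_geneset):
        out = tmp_path / "same.gtf"
        write_enhanced_annotation([], tiny_geneset, None, out)
        reloaded = load_annotation(out)
        assert set(reloaded.transcripts) == set(tiny_geneset.transcripts)
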