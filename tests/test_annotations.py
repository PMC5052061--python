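"""Annotation parsing, union gene models, and end extension."""

import logging

import pytest
from hypothesis import given, settings, strategies as st

from endseq.annotations import (
    GeneModel,
    TranscriptRecord,
    build_gene_models,
    extend_gene_model,
    extend_gene_models,
    merge_intervals,
    read_bed,
    read_gene_table,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return str(path)


class TestReadBed:
    def test_bed12_blocks_preserved(self, tmp_path):
        path = _write(
            tmp_path,
            "a.bed",
            "chr1\t100\t500\ttx1\t0\t+\t100\t500\t0\t2\t50,100,\t0,300,\n",
        )
        (rec,) = read_bed(path)
        assert rec.exons == [(100, 150), (400, 500)]
        assert (rec.tx_start, rec.tx_end, rec.strand) == (100, 500, "+")

    def test_bed6_single_exon(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t100\t500\ttx1\t0\t-\n")
        (rec,) = read_bed(path)
        assert rec.exons == [(100, 500)]

    def test_dot_strand_rejected(self, tmp_path):
        path = _write(tmp_path, "a.bed", "chr1\t100\t500\ttx1\t0\t.\n")
        with pytest.raises(ValueError, match="line 1.*strand"):
            read_bed(path)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = _write(
            tmp_path,
            "a.bed",
            "chr1\t100\t500\ttx1\t0\t+\nchr1\tBAD\t600\ttx2\t0\t+\n",
        )
        with pytest.raises(ValueError, match="line 2"):
            read_bed(path)


class TestReadGeneTable:
    HEADER = "#name\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname2\n"

    def test_trailing_comma_dialect(self, tmp_path):
        path = _write(
            tmp_path,
            "t.txt",
            self.HEADER + "tx1\tchr1\t+\t100\t600\t100,500,\t200,600,\tGENE\n",
        )
        (rec,) = read_gene_table(path)
        assert rec.exons == [(100, 200), (500, 600)]
        assert rec.gene_symbol == "GENE"

    def test_two_isoforms_share_symbol(self, tmp_path):
        path = _write(
            tmp_path,
            "t.txt",
            self.HEADER
            + "tx1\tchr1\t+\t100\t600\t100,\t600,\tGENE\n"
            + "tx2\tchr1\t+\t100\t700\t100,\t700,\tGENE\n",
        )
        recs = read_gene_table(path)
        assert [r.gene_symbol for r in recs] == ["GENE", "GENE"]
        assert [r.transcript_id for r in recs] == ["tx1", "tx2"]

    def test_mismatched_exon_lists_error(self, tmp_path):
        path = _write(
            tmp_path,
            "t.txt",
            self.HEADER + "tx1\tchr1\t+\t100\t600\t100,500,\t200,\tGENE\n",
        )
        with pytest.raises(ValueError, match="mismatch"):
            read_gene_table(path)

    def test_missing_column_listed(self, tmp_path):
        path = _write(
            tmp_path,
            "t.txt",
            "name\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\n"
            "tx1\tchr1\t+\t100\t600\t100,\t600,\n",
        )
        with pytest.raises(ValueError, match="name2"):
            read_gene_table(path)

    def test_extra_columns_ignored(self, tmp_path):
        path = _write(
            tmp_path,
            "t.txt",
            "#bin\tname\tchrom\tstrand\ttxStart\ttxEnd\texonStarts\texonEnds\tname2\textra\n"
            "0\ttx1\tchr1\t+\t100\t600\t100,\t600,\tGENE\tx\n",
        )
        (rec,) = read_gene_table(path)
        assert rec.gene_symbol == "GENE"


def _tx(tid, symbol, exons, strand="+", chrom="chr1"):
    return TranscriptRecord(
        transcript_id=tid,
        gene_symbol=symbol,
        chrom=chrom,
        strand=strand,
        tx_start=exons[0][0],
        tx_end=exons[-1][1],
        exon_starts=[s for s, _ in exons],
        exon_ends=[e for _, e in exons],
    )


class TestBuildGeneModels:
    def test_union_of_isoform_exons(self):
        a = _tx("a", "G", [(0, 100), (200, 300)])
        b = _tx("b", "G", [(50, 120), (200, 350)])
        (model,) = build_gene_models([a, b])
        assert model.exonic_blocks == [(0, 120), (200, 350)]

    def test_strand_conflict_drops_isoform_with_warning(self, caplog):
        a = _tx("a", "G", [(0, 100)], strand="+")
        b = _tx("b", "G", [(50, 120)], strand="-")
        with caplog.at_level(logging.WARNING, logger="endseq"):
            (model,) = build_gene_models([a, b])
        assert model.exonic_blocks == [(0, 100)]
        assert model.strand == "+"
        assert any("New isoform mismatch for G" in m for m in caplog.messages)

    def test_single_isoform_identity(self):
        a = _tx("a", "G", [(10, 50), (80, 120)])
        (model,) = build_gene_models([a])
        assert model.exonic_blocks == a.exons
        assert model.effective_length == 80

    def test_per_transcript_mode_keeps_isoforms_separate(self):
        a = _tx("a", "G", [(0, 100)])
        b = _tx("b", "G", [(0, 100)])
        models = build_gene_models([a, b], "per_transcript")
        assert sorted(m.gene_symbol for m in models) == ["a", "b"]

    def test_union_length_at_least_each_isoform(self):
        a = _tx("a", "G", [(0, 100), (200, 300)])
        b = _tx("b", "G", [(50, 250)])
        (model,) = build_gene_models([a, b])
        for iso in (a, b):
            assert model.exonic_length >= sum(e - s for s, e in iso.exons)

    @given(
        st.permutations(
            [
                [(0, 100), (200, 300)],
                [(50, 120), (200, 350)],
                [(90, 110)],
            ]
        )
    )
    @settings(max_examples=6, deadline=None)
    def test_block_union_is_order_insensitive(self, exon_sets):
        records = [_tx(f"t{i}", "G", exons) for i, exons in enumerate(exon_sets)]
        (model,) = build_gene_models(records)
        assert model.exonic_blocks == [(0, 120), (200, 350)]

    def test_idempotent_interval_union(self):
        blocks = [(0, 120), (200, 350)]
        assert merge_intervals(blocks) == blocks


def _gene(symbol, exons, strand="+"):
    return GeneModel(
        gene_symbol=symbol, chrom="chr1", strand=strand,
        exonic_blocks=list(exons),
    )


class TestExtension:
    def test_truncated_at_same_strand_neighbor(self):
        g = _gene("A", [(0, 1000)])
        nb = _gene("B", [(3000, 4000)])
        ext = extend_gene_model(g, 5000, "score3p", [g, nb])
        assert ext.extension_block == (1000, 3000)
        assert ext.effective_length == 1000 + 2000

    def test_zero_extension_is_identity(self):
        g = _gene("A", [(0, 1000)])
        ext = extend_gene_model(g, 0, "score3p", [])
        assert ext.extension_block is None
        assert ext.exonic_blocks == g.exonic_blocks

    def test_minus_strand_three_prime_extends_left(self):
        g = _gene("A", [(5000, 6000)], strand="-")
        ext = extend_gene_model(g, 2000, "score3p", [])
        assert ext.extension_block == (3000, 5000)

    def test_five_prime_task_mirrors_direction(self):
        g = _gene("A", [(5000, 6000)], strand="+")
        ext = extend_gene_model(g, 1000, "score5p", [])
        assert ext.extension_block == (4000, 5000)

    def test_opposite_strand_neighbor_never_truncates(self):
        g = _gene("A", [(0, 1000)])
        nb = _gene("B", [(1500, 2500)], strand="-")
        ext = extend_gene_model(g, 5000, "score3p", [nb])
        assert ext.extension_block == (1000, 6000)

    def test_abutting_genes_give_empty_extension(self):
        g = _gene("A", [(0, 1000)])
        nb = _gene("B", [(1000, 2000)])
        ext = extend_gene_model(g, 5000, "score3p", [nb])
        assert ext.extension_block is None

    @given(
        starts=st.lists(
            st.integers(min_value=0, max_value=200), min_size=2, max_size=6,
            unique=True,
        ),
        w_ext=st.integers(min_value=0, max_value=5000),
    )
    @settings(max_examples=60, deadline=None)
    def test_extended_same_strand_models_stay_disjoint(self, starts, w_ext):
        models = [
            _gene(f"G{i}", [(s * 100, s * 100 + 50)])
            for i, s in enumerate(sorted(starts))
        ]
        extended = extend_gene_models(models, w_ext, "score3p")
        spans = sorted(
            (m.all_blocks[0][0], m.all_blocks[-1][1]) for m in extended
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestGeneModelCoordinates:
    def test_offset_round_trip_across_intron(self):
        g = _gene("A", [(0, 10), (20, 30)])
        assert g.genomic_to_offset(5) == 5
        assert g.genomic_to_offset(20) == 10
        assert g.genomic_to_offset(15) is None
        for off in range(g.effective_length):
            assert g.genomic_to_offset(g.offset_to_genomic(off)) == off

    def test_extension_contributes_to_length_and_lookup(self):
        g = GeneModel(
            gene_symbol="A", chrom="chr1", strand="+",
            exonic_blocks=[(0, 100)], extension_block=(100, 150),
        )
        assert g.effective_length == 150
        assert g.contains(120)
        assert g.genomic_to_offset(120) == 120
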