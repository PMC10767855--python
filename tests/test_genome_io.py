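"""Genome/annotation parsing, coordinate maps and format writers."""

import numpy as np
import pytest

from altorf.genome_io import merge_annotations, read_annotation, read_genome, spliced_sequence
from altorf.models import Exon, GenomeSequences, Transcript, revcomp
from altorf.orfs import enumerate_orfs
from altorf.writers import read_bed_blocks, write_orf_bed


def make_tx(exons, strand="+", tx_id="t1", gene_id="g1", **kw):
    ordered = sorted(exons, key=lambda se: se[0], reverse=strand == "-")
    return Transcript(
        tx_id, gene_id, kw.get("gene_name", ""), kw.get("biotype", "protein_coding"),
        "test", strand, [Exon("chr1", s, e, strand) for s, e in ordered],
    )


class TestReadGenome:
    def test_case_and_u_normalisation(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nacgu\n")
        g = read_genome(str(p))
        assert g.fetch("chr1") == "ACGT"

    def test_two_records(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACGT\n>b\nGGCC\n")
        assert sorted(read_genome(str(p)).names()) == ["a", "b"]

    def test_duplicate_name_errors(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">a\nACGT\n>a\nGGCC\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genome(str(p))

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome(str(p))

    def test_chr_prefix_tolerated(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        g = read_genome(str(p))
        assert g.fetch("1") == "ACGT"
        assert "1" in g and "chr1" in g


GFF3 = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t{strand}\t.\tID=g1;gene_id=g1;gene_name=FOO
chr1\tsrc\ttranscript\t101\t400\t.\t{strand}\t.\tID=t1;Parent=g1;gene_id=g1;gene_name=FOO;biotype=protein_coding
chr1\tsrc\texon\t101\t200\t.\t{strand}\t.\tParent=t1
chr1\tsrc\texon\t301\t400\t.\t{strand}\t.\tParent=t1
"""

GTF = """chr1\tsrc\tgene\t101\t400\t.\t{strand}\t.\tgene_id "g1"; gene_name "FOO";
chr1\tsrc\ttranscript\t101\t400\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1"; gene_name "FOO"; transcript_biotype "protein_coding";
chr1\tsrc\texon\t101\t200\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t400\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1";
"""


class TestReadAnnotation:
    def test_one_based_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3.format(strand="+"))
        (tx,) = read_annotation(str(p), "ensembl-like")
        assert (tx.exons[0].start, tx.exons[0].end) == (100, 200)
        assert tx.biotype == "protein_coding"

    def test_minus_strand_exon_order(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3.format(strand="-"))
        (tx,) = read_annotation(str(p), "ensembl-like")
        assert [(e.start, e.end) for e in tx.exons] == [(300, 400), (100, 200)]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_gtf_gff3_dialect_equivalence(self, tmp_path, strand):
        a = tmp_path / "a.gff3"
        b = tmp_path / "a.gtf"
        a.write_text(GFF3.format(strand=strand))
        b.write_text(GTF.format(strand=strand))
        (t1,) = read_annotation(str(a), "x")
        (t2,) = read_annotation(str(b), "x")
        assert t1.exons == t2.exons
        assert (t1.gene_id, t1.biotype, t1.strand) == (t2.gene_id, t2.biotype, t2.strand)

    def test_orphan_exon_skipped_with_warning(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3.format(strand="+") + "chr1\tsrc\texon\t501\t600\t.\t+\t.\tParent=nope\n")
        with pytest.warns(UserWarning, match="no parent"):
            (tx,) = read_annotation(str(p), "x")
        assert len(tx.exons) == 2

    def test_transcript_without_exons_gets_span(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\ttranscript\t11\t50\t.\t+\t.\tID=t9;gene_id=g9\n"
        )
        (tx,) = read_annotation(str(p), "x")
        assert [(e.start, e.end) for e in tx.exons] == [(10, 50)]


class TestTranscriptModel:
    def test_multichrom_exons_rejected(self):
        with pytest.raises(ValueError, match="chromosom"):
            Transcript("t", "g", "", "", "x", "+",
                       [Exon("chr1", 0, 10, "+"), Exon("chr2", 20, 30, "+")])

    def test_map_to_genomic_examples(self):
        t = make_tx([(100, 200), (300, 400)])
        assert t.to_genomic(0) == 100
        assert t.to_genomic(100) == 300
        tm = make_tx([(100, 200)], strand="-")
        assert tm.to_genomic(0) == 199

    def test_out_of_range_errors(self):
        t = make_tx([(100, 200)])
        with pytest.raises(ValueError):
            t.to_genomic(100)
        with pytest.raises(ValueError):
            t.to_transcript(250)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_random_transcripts(self, strand):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_ex = int(rng.integers(1, 5))
            cursor, exons = 0, []
            for _ in range(n_ex):
                cursor += int(rng.integers(1, 50))
                length = int(rng.integers(1, 80))
                exons.append((cursor, cursor + length))
                cursor += length
            t = make_tx(exons, strand=strand)
            for x in range(t.spliced_length):
                assert t.to_transcript(t.to_genomic(x)) == x


class TestSplicedSequence:
    def test_plus_strand_concatenation(self):
        g = GenomeSequences({"chr1": "ATGCCCTAA"})
        t = make_tx([(0, 3), (6, 9)])
        assert spliced_sequence(t, g) == "ATGTAA"

    def test_minus_strand_revcomp(self):
        g = GenomeSequences({"chr1": "ATGCAT"})
        t = make_tx([(0, 6)], strand="-")
        assert spliced_sequence(t, g) == "ATGCAT"  # palindromic construction

    def test_missing_chromosome_errors(self):
        g = GenomeSequences({"chr2": "ACGT"})
        t = make_tx([(0, 4)])
        with pytest.raises(KeyError):
            spliced_sequence(t, g)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_multi_exon_vs_string_oracle(self, strand):
        rng = np.random.default_rng(3)
        for _ in range(50):
            chrom = "".join(rng.choice(list("ACGT"), size=400))
            g = GenomeSequences({"chr1": chrom})
            cursor, exons = 0, []
            for _ in range(int(rng.integers(1, 4))):
                cursor += int(rng.integers(1, 40))
                length = int(rng.integers(3, 60))
                exons.append((cursor, cursor + length))
                cursor += length
            t = make_tx(exons, strand=strand)
            plus = "".join(chrom[s:e] for s, e in exons)
            expected = plus if strand == "+" else revcomp(plus)
            assert spliced_sequence(t, g) == expected


class TestMergeAnnotations:
    def test_merge_by_gene_name(self):
        a = [make_tx([(0, 300)], gene_id="ENSG1", gene_name="FOO")]
        b = [make_tx([(1000, 1300)], tx_id="t2", gene_id="XM_1", gene_name="foo")]
        merged = merge_annotations(a, b)
        assert {t.gene_id for t in merged} == {"ENSG1"}

    def test_merge_by_overlap_same_strand(self):
        a = [make_tx([(0, 300)], gene_id="ENSG1", gene_name="FOO")]
        b = [make_tx([(100, 200)], tx_id="t2", gene_id="XM_1", gene_name="BAR")]
        merged = merge_annotations(a, b)
        assert {t.gene_id for t in merged} == {"ENSG1"}

    def test_opposite_strand_overlap_not_merged(self):
        a = [make_tx([(0, 300)], gene_id="ENSG1", gene_name="FOO")]
        b = [make_tx([(100, 200)], tx_id="t2", gene_id="XM_1", gene_name="BAR", strand="-")]
        merged = merge_annotations(a, b)
        assert {t.gene_id for t in merged} == {"ENSG1", "XM_1"}


class TestBedWriter:
    def test_single_exon_orf_block(self, tmp_path):
        g = GenomeSequences({"chr1": "A" * 100})
        t = make_tx([(0, 100)])
        seq = "T" * 3 + "ATG" + "GCT" * 28 + "TAA" + "T" * 4
        orfs = enumerate_orfs(t, seq)
        path = tmp_path / "o.bed"
        write_orf_bed(orfs, str(path))
        (name, blocks), = read_bed_blocks(str(path))
        assert blocks == [("chr1", 3, 93, "+")]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_blocks_sum_and_round_trip(self, tmp_path, strand):
        rng = np.random.default_rng(9)
        seq = "T" * 10 + "ATG" + "GCT" * 40 + "TAA" + "T" * 10
        n = len(seq)
        cut = 60
        exons = [(50, 50 + cut), (200, 200 + n - cut)]
        t = make_tx(exons, strand=strand)
        orfs = enumerate_orfs(t, seq)
        assert orfs, "construction must yield an ORF spanning the intron"
        path = tmp_path / "o.bed"
        write_orf_bed(orfs, str(path))
        parsed = read_bed_blocks(str(path))
        for orf, (_, blocks) in zip(orfs, parsed):
            assert sorted(blocks) == sorted(orf.genomic_blocks)
            assert sum(e - s for _, s, e, _ in blocks) == 3 * orf.codon_count
            assert len(blocks) == 2
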