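"""Per-ORF variant consequence calls: VCF parsing, frame-aware effects,
strand symmetry and the mutate→retranslate oracle."""

import numpy as np
import pytest

from altorf.models import Exon, GenomeSequences, Transcript, revcomp
from altorf.oracles import oracle_project_edit, oracle_variant_consequence
from altorf.orfs import enumerate_orfs
from altorf.variants import (
    IMPACT_OF,
    VariantRecord,
    annotate_variant,
    normalize_variant,
    read_vcf,
    summarize_impacts,
)

SENSE = "GCT"


def single_exon_setup(seq, strand="+", chrom_pad=7):
    """Genome carrying ``seq`` as one exon (strand-aware) plus padding."""
    if strand == "+":
        chrom = "T" * chrom_pad + seq + "T" * chrom_pad
    else:
        chrom = "T" * chrom_pad + revcomp(seq) + "T" * chrom_pad
    genome = GenomeSequences({"chr1": chrom})
    t = Transcript(
        "t1", "g1", "", "protein_coding", "x", strand,
        [Exon("chr1", chrom_pad, chrom_pad + len(seq), strand)],
    )
    orfs = enumerate_orfs(t, seq)
    return genome, t, orfs


def call_one(genome, t, orfs, pos, ref, alt):
    v = VariantRecord("chr1", pos, ref, alt, "v1")
    assert genome.fetch("chr1", pos, pos + len(ref)) == ref
    seq_map = {"t1": "".join(
        genome.fetch("chr1", e.start, e.end) if t.strand == "+" else revcomp(genome.fetch("chr1", e.start, e.end))
        for e in t.exons
    )}
    return annotate_variant(v, {"t1": orfs}, {"t1": t}, seq_map)


class TestReadVcf:
    def _write(self, tmp_path, body, chrom_len=50):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID=chr1,length={chrom_len}>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body
        )
        return str(p)

    def test_coordinate_shift(self, tmp_path):
        genome = GenomeSequences({"chr1": "T" * 10 + "A" + "T" * 39})
        path = self._write(tmp_path, "chr1\t11\t.\tA\tG\t.\tPASS\t.\n")
        (v,) = read_vcf(path, genome)
        assert (v.pos, v.ref, v.alt) == (10, "A", "G")

    def test_multiallelic_split(self, tmp_path):
        genome = GenomeSequences({"chr1": "T" * 10 + "A" + "T" * 39})
        path = self._write(tmp_path, "chr1\t11\t.\tA\tG,C\t.\tPASS\t.\n")
        vs = read_vcf(path, genome)
        assert [v.alt for v in vs] == ["G", "C"]

    def test_ref_mismatch_errors_with_position(self, tmp_path):
        genome = GenomeSequences({"chr1": "T" * 50})
        path = self._write(tmp_path, "chr1\t11\t.\tA\tG\t.\tPASS\t.\n")
        with pytest.raises(ValueError, match="chr1:11"):
            read_vcf(path, genome)

    def test_left_normalization_of_indel(self):
        genome = GenomeSequences({"chr1": "TTTAAAAGGG"})
        # deleting one A of the A-run left-aligns to the anchor base before it
        v = normalize_variant(VariantRecord("chr1", 5, "AA", "A"), genome)
        assert (v.pos, v.ref, v.alt) == (2, "TA", "T")


class TestConsequenceExamples:
    def test_synonymous_snv(self):
        seq = "ATG" + "AAA" + SENSE * 27 + "TAA"
        genome, t, orfs = single_exon_setup(seq)
        (call,) = [c for c in call_one(genome, t, orfs, 7 + 5, "A", "G")]
        assert (call.consequence, call.impact) == ("synonymous", "low")  # AAA→AAG

    def test_missense_snv(self):
        seq = "ATG" + "AAA" + SENSE * 27 + "TAA"
        genome, t, orfs = single_exon_setup(seq)
        (call,) = call_one(genome, t, orfs, 7 + 3, "A", "G")  # AAA→GAA K→E
        assert (call.consequence, call.impact) == ("missense", "moderate")

    def test_one_nt_insertion_is_frameshift(self):
        seq = "ATG" + SENSE * 30 + "TAA"
        genome, t, orfs = single_exon_setup(seq)
        pos = 7 + 10
        ref = genome.fetch("chr1", pos, pos + 1)
        alt = ref + ("A" if ref != "A" else "C")
        (call,) = call_one(genome, t, orfs, pos, ref, alt)
        assert (call.consequence, call.impact) == ("frameshift", "high")

    def test_inframe_deletion(self):
        seq = "ATG" + SENSE * 30 + "TAA"
        genome, t, orfs = single_exon_setup(seq)
        pos = 7 + 9  # codon boundary anchored deletion of one codon
        ref = genome.fetch("chr1", pos, pos + 4)
        (call,) = call_one(genome, t, orfs, pos, ref, ref[0])
        assert (call.consequence, call.impact) == ("inframe_deletion", "moderate")

    def test_stop_lost(self):
        seq = "ATG" + SENSE * 29 + "TAA" + SENSE * 5 + "TGA"  # downstream in-frame stop
        genome, t, orfs = single_exon_setup(seq)
        stop_pos = 7 + 3 + 29 * 3
        (call,) = call_one(genome, t, orfs, stop_pos, "T", "C")
        assert (call.consequence, call.impact) == ("stop_lost", "high")

    def test_stop_gained(self):
        seq = "ATG" + "TAC" * 30 + "TAA"  # Tyr codons: TAC→TAA with C→A
        genome, t, orfs = single_exon_setup(seq)
        pos = 7 + 3 + 2  # third base of first Tyr codon
        (call,) = call_one(genome, t, orfs, pos, "C", "A")
        assert (call.consequence, call.impact) == ("stop_gained", "high")

    def test_start_lost(self):
        seq = "ATG" + SENSE * 29 + "TAA"
        genome, t, orfs = single_exon_setup(seq)
        (call,) = call_one(genome, t, orfs, 7, "A", "G")
        assert (call.consequence, call.impact) == ("start_lost", "high")

    def test_variant_outside_orf_is_modifier(self):
        seq = "TTTTTT" + "ATG" + SENSE * 29 + "TAA" + "TTTTTT"
        genome, t, orfs = single_exon_setup(seq)
        (call,) = call_one(genome, t, orfs, 7 + 1, "T", "A")
        assert (call.consequence, call.impact) == ("non_orf", "modifier")

    def test_synonymous_stop_swap(self):
        seq = "ATG" + SENSE * 29 + "TAA"
        genome, t, orfs = single_exon_setup(seq)
        third = 7 + 3 + 29 * 3 + 2  # TAA→TAG
        (call,) = call_one(genome, t, orfs, third, "A", "G")
        assert call.consequence == "synonymous"


class TestFrameOverlap:
    def test_divergent_consequences_reported_independently(self, study_result):
        res, truth, _ = study_result
        by_variant = {}
        for c in res.consequence_calls:
            if c.consequence != "non_orf":
                by_variant.setdefault(c.variant_key, set()).add(c.consequence)
        divergent = [k for k, v in by_variant.items() if len(v) >= 2]
        assert divergent, "fixture plants variants hitting overlapping frames"

    def test_impact_always_matches_fixed_mapping(self, study_result):
        res, _, _ = study_result
        for c in res.consequence_calls:
            assert c.impact == IMPACT_OF[c.consequence]


class TestStrandSymmetry:
    @pytest.mark.parametrize(
        "offset,ref,alt,expected",
        [(5, "A", "G", "synonymous"), (3, "A", "G", "missense")],
    )
    def test_same_biology_both_strands(self, offset, ref, alt, expected):
        seq = "ATG" + "AAA" + SENSE * 27 + "TAA"
        g_plus, t_plus, orfs_plus = single_exon_setup(seq, "+")
        (cp,) = call_one(g_plus, t_plus, orfs_plus, 7 + offset, ref, alt)
        g_minus, t_minus, orfs_minus = single_exon_setup(seq, "-")
        # mirror the variant: genomic position and complemented alleles
        pos_minus = 7 + len(seq) - 1 - offset
        (cm,) = call_one(g_minus, t_minus, orfs_minus, pos_minus, revcomp(ref), revcomp(alt))
        assert cp.consequence == cm.consequence == expected


class TestOracleEquivalence:
    def test_random_variants_match_oracle(self, mini_fixture, mini_result):
        d, truth = mini_fixture
        res, _ = mini_result
        from altorf.genome_io import read_genome

        genome = read_genome(f"{d}/genome.fa")
        rng = np.random.default_rng(55)
        checked = 0
        tx_ids = [tx for tx, orfs in res.orfs_by_transcript.items() if orfs]
        while checked < 150:
            tx_id = tx_ids[int(rng.integers(0, len(tx_ids)))]
            t = res.transcripts[tx_id]
            seq = res.spliced[tx_id]
            gpos = [t.to_genomic(i) for i in range(t.spliced_length)]
            g = int(rng.integers(t.genomic_start, t.genomic_end - 4))
            kind = rng.random()
            if kind < 0.6:
                ref = genome.fetch(t.chrom, g, g + 1)
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            elif kind < 0.8:
                ref = genome.fetch(t.chrom, g, g + 1)
                ins = str(rng.choice([b for b in "ACGT" if b != ref]))
                alt = ref + ins
            else:
                ref = genome.fetch(t.chrom, g, g + int(rng.integers(2, 5)))
                alt = ref[0]
            v = VariantRecord(t.chrom, g, ref, alt, f"rv{checked}")
            calls = annotate_variant(v, {tx_id: res.orfs_by_transcript[tx_id]},
                                     res.transcripts, res.spliced)
            edit = oracle_project_edit(gpos, t.strand, g, ref, alt)
            for call in calls:
                orf = next(o for o in res.orfs_by_transcript[tx_id] if o.orf_id == call.orf_id)
                expected = oracle_variant_consequence(seq, orf.t_start, orf.t_end, edit)
                assert call.consequence == expected, (v, call.orf_id)
                checked += 1


class TestSummarize:
    def test_worst_impact_ordering(self, study_result):
        res, _, _ = study_result
        worst, tally = summarize_impacts(
            res.consequence_calls, {cp.accession: cp.cls for cp in res.proteins}
        )
        rank = {"high": 3, "moderate": 2, "low": 1, "modifier": 0}
        for key, impact in worst.items():
            impacts = [c.impact for c in res.consequence_calls if c.variant_key == key]
            assert rank[impact] == max(rank[i] for i in impacts)
        assert set(i for _, i in tally) <= {"high", "moderate", "low", "modifier"}

    def test_only_non_orf_calls_worst_is_modifier(self):
        from altorf.variants import ConsequenceCall

        calls = [ConsequenceCall("v1", "IP_1", "t1:0-90", "t1", "non_orf", "modifier")]
        worst, _ = summarize_impacts(calls)
        assert worst == {"v1": "modifier"}
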