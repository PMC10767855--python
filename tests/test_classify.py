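"""Protein classification, accession minting and reference promotion."""

import numpy as np
import pytest

from altorf.classify import (
    ALTPROT,
    NOVEL_ISOFORM,
    REFPROT,
    ClassifiedProtein,
    ReferenceProteome,
    classify,
    local_identity,
    mint_accessions,
    promote_to_reference,
)
from altorf.models import Exon, Transcript
from altorf.oracles import gotoh_local
from altorf.orfs import OrfCandidate, ProteinRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")


def protein_record(sequence, genes={"g1"}, start=100):
    orf = OrfCandidate(
        "t1", 0, 0, 3 * (len(sequence) + 1), len(sequence) + 1,
        [("chr1", start, start + 3 * (len(sequence) + 1), "+")], sequence,
    )
    rec = ProteinRecord(sequence=sequence, orfs=[orf], genes=set(genes), transcripts={"t1"})
    return rec


def ref_with(*entries):
    ref = ReferenceProteome()
    for acc, genes, seq in entries:
        ref.add(acc, frozenset(genes), seq)
    return ref


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(99)


class TestClassify:
    def test_exact_match_is_refprot(self, rng):
        seq = "".join(rng.choice(AA, size=80))
        ref = ref_with(("REF1", {"g1"}, seq))
        cp = classify(protein_record(seq), ref)
        assert cp.cls == REFPROT and cp.accession == "REF1"

    def test_internal_deletion_is_novel_isoform(self, rng):
        full = "".join(rng.choice(AA, size=200))
        deleted = full[:95] + full[105:]
        ref = ref_with(("REF1", {"g1"}, full))
        cp = classify(protein_record(deleted), ref)
        assert cp.cls == NOVEL_ISOFORM
        assert cp.best_ref_hit[0] == "REF1"
        assert cp.best_ref_hit[1] > 0.95

    def test_unrelated_sequence_is_altprot(self, rng):
        ref = ref_with(("REF1", {"g1"}, "".join(rng.choice(AA, size=120))))
        cp = classify(protein_record("".join(rng.choice(AA, size=40))), ref)
        assert cp.cls == ALTPROT

    def test_gene_locality_blocks_novel_isoform(self, rng):
        full = "".join(rng.choice(AA, size=200))
        deleted = full[:95] + full[105:]
        ref = ref_with(("REF1", {"gOTHER"}, full))
        cp = classify(protein_record(deleted, genes={"g1"}), ref)
        assert cp.cls == ALTPROT  # high similarity but different gene

    def test_exact_match_other_gene_still_refprot(self, rng):
        seq = "".join(rng.choice(AA, size=60))
        ref = ref_with(("REF1", {"gOTHER"}, seq))
        cp = classify(protein_record(seq, genes={"g1"}), ref)
        assert cp.cls == REFPROT and cp.cross_locus_note

    def test_threshold_sweep_on_partial_homolog(self, rng):
        # ~60% identical homolog: novel isoform at a 0.5 identity threshold,
        # altprot at the 0.8 default
        base = "".join(rng.choice(AA, size=100))
        mutant = list(base)
        positions = rng.choice(100, size=40, replace=False)
        for i in positions:
            mutant[i] = str(rng.choice([a for a in AA if a != mutant[i]]))
        mutant = "".join(mutant)
        _, identity, coverage = gotoh_local(mutant, base)
        assert 0.5 < identity < 0.8 and coverage > 0.5
        ref = ref_with(("REF1", {"g1"}, base))
        assert classify(protein_record(mutant), ref, id_threshold=0.5).cls == NOVEL_ISOFORM
        assert classify(protein_record(mutant), ref, id_threshold=0.8).cls == ALTPROT

    def test_exact_match_supremacy_over_thresholds(self, rng):
        seq = "".join(rng.choice(AA, size=50))
        ref = ref_with(("REF1", {"g1"}, seq))
        cp = classify(protein_record(seq), ref, id_threshold=1.1, cov_threshold=1.1)
        assert cp.cls == REFPROT

    def test_partition_single_class(self, mini_result):
        res, truth = mini_result
        assert all(cp.cls in (REFPROT, NOVEL_ISOFORM, ALTPROT) for cp in res.proteins)
        from collections import Counter

        counts = Counter(cp.cls for cp in res.proteins)
        assert sum(counts.values()) == len(res.proteins)


class TestAlignerAgreement:
    def test_identity_matches_independent_dp(self, rng):
        for _ in range(40):
            a = "".join(rng.choice(AA, size=int(rng.integers(30, 150))))
            if rng.random() < 0.5:
                b = list(a)
                for _ in range(int(rng.integers(1, 12))):
                    b[int(rng.integers(0, len(b)))] = str(rng.choice(AA))
                b = "".join(b)
            else:
                b = "".join(rng.choice(AA, size=int(rng.integers(30, 150))))
            s1, i1, _ = local_identity(a, b)
            s2, i2, _ = gotoh_local(a, b)
            assert s1 == pytest.approx(s2)
            assert i1 == pytest.approx(i2, abs=0.05)


class TestMintAccessions:
    def _set(self, rng):
        cps = []
        for i, (cls, chrom) in enumerate(
            [(ALTPROT, "chr1"), (ALTPROT, "chr2"), (NOVEL_ISOFORM, "chr1"), (ALTPROT, "chr1")]
        ):
            seq = "".join(rng.choice(AA, size=35))
            rec = protein_record(seq, start=1000 * (i + 1))
            rec.orfs[0].genomic_blocks = [(chrom, 1000 * (i + 1), 1000 * (i + 1) + 108, "+")]
            cps.append(ClassifiedProtein(record=rec, cls=cls))
        return cps

    def test_genomic_order_and_prefixes(self, rng):
        out = mint_accessions(self._set(rng))
        ips = [cp for cp in out if cp.cls == ALTPROT]
        assert [cp.accession for cp in ips] == ["IP_1", "IP_2", "IP_3"]
        # chr1 before chr2
        assert ips[0].record.orfs[0].genomic_blocks[0][0] == "chr1"
        assert ips[-1].record.orfs[0].genomic_blocks[0][0] == "chr2"
        (ii,) = [cp for cp in out if cp.cls == NOVEL_ISOFORM]
        assert ii.accession == "II_1"

    def test_permutation_invariance(self, rng):
        cps = self._set(rng)
        a = {cp.sequence: cp.accession for cp in mint_accessions(list(cps))}
        shuffled = list(cps)[::-1]
        b = {cp.sequence: cp.accession for cp in mint_accessions(shuffled)}
        assert a == b


class TestPromoteToReference:
    def test_planted_transitions_counted(self, rng):
        cps = []
        seqs = ["".join(rng.choice(AA, size=40)) for _ in range(5)]
        for seq in seqs:
            cps.append(ClassifiedProtein(record=protein_record(seq), cls=ALTPROT, accession="IP_x"))
        new_ref = ref_with(("NEW1", {"g1"}, seqs[0]), ("NEW2", {"g1"}, seqs[3]))
        report = promote_to_reference(cps, new_ref)
        assert report == {"altprot->refprot": 2}
        assert sum(1 for cp in cps if cp.cls == REFPROT) == 2

    def test_empty_delta_empty_report(self, rng):
        cps = [ClassifiedProtein(record=protein_record("".join(rng.choice(AA, size=40))), cls=ALTPROT)]
        assert promote_to_reference(cps, ReferenceProteome()) == {}
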