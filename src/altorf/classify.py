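"""Three-class protein classification and stable accession minting.

A predicted protein is a *reference protein* when its sequence exactly
matches an entry of the reference proteome (Ensembl-, RefSeq- and/or
UniProt-like FASTAs pooled); a *novel isoform* (accession ``II_``) when it
shows substantial similarity to a reference protein encoded in the same
gene; otherwise an *alternative protein* (accession ``IP_``).

"Substantial similarity" is operationalised as a Smith–Waterman local
alignment (BLOSUM62, gap open 11 / extend 1) with identity ≥ ``id_threshold``
over an aligned region covering ≥ ``cov_threshold`` of the shorter sequence;
both thresholds are explicit knobs recorded in output metadata.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .orfs import ProteinRecord

DEFAULT_ID_THRESHOLD = 0.80
DEFAULT_COV_THRESHOLD = 0.50

REFPROT = "refprot"
NOVEL_ISOFORM = "novel_isoform"
ALTPROT = "altprot"


@dataclass
class ReferenceProteome:
    """Reference protein entries with exact-sequence and per-gene indexes."""

    entries: list[tuple[str, frozenset[str], str]] = field(default_factory=list)
    _by_seq: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _by_gene: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def add(self, accession: str, genes: frozenset[str], sequence: str) -> None:
        if any(acc == accession for acc, _, _ in self.entries):
            raise ValueError(f"duplicate reference accession {accession!r}")
        idx = len(self.entries)
        self.entries.append((accession, genes, sequence))
        self._by_seq.setdefault(sequence, []).append(idx)
        for g in genes:
            self._by_gene.setdefault(g, []).append(idx)

    @classmethod
    def from_fastas(cls, *paths: str) -> "ReferenceProteome":
        """Pool one or more reference FASTAs; ``GN=`` header tokens give genes."""
        ref = cls()
        for path in paths:
            for record in SeqIO.parse(str(path), "fasta"):
                genes = frozenset(re.findall(r"GN=(\S+)", record.description))
                ref.add(record.id, genes, str(record.seq))
        return ref

    def exact_matches(self, sequence: str) -> list[tuple[str, frozenset[str], str]]:
        return [self.entries[i] for i in self._by_seq.get(sequence, [])]

    def entries_for_genes(self, genes: set[str]) -> list[tuple[str, frozenset[str], str]]:
        idxs = sorted({i for g in genes for i in self._by_gene.get(g, [])})
        return [self.entries[i] for i in idxs]

    def contains_substring(self, peptide: str) -> bool:
        return any(peptide in seq for _, _, seq in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ClassifiedProtein:
    """A ProteinRecord plus class, accession and best reference hit."""

    record: ProteinRecord
    cls: str
    accession: str = ""
    best_ref_hit: tuple[str, float, float] | None = None  # (ref_acc, identity, coverage)
    cross_locus_note: str = ""

    @property
    def sequence(self) -> str:
        return self.record.sequence


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def local_identity(a: str, b: str) -> tuple[float, float, float]:
    """Best local-alignment (score, identity, coverage-of-shorter) for a pair.

    Identity is matches / aligned columns of the best-scoring alignment;
    coverage is aligned residue pairs / length of the shorter sequence.
    """
    if not a or not b:
        return 0.0, 0.0, 0.0
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return score, 0.0, 0.0
    aln = next(iter(_ALIGNER.align(a, b)))
    counts = aln.counts()
    aligned_pairs = counts.identities + counts.mismatches
    if aligned_pairs == 0:
        return score, 0.0, 0.0
    identity = counts.identities / aligned_pairs
    coverage = aligned_pairs / min(len(a), len(b))
    return score, identity, coverage


def classify(
    p: ProteinRecord,
    ref: ReferenceProteome,
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    cov_threshold: float = DEFAULT_COV_THRESHOLD,
) -> ClassifiedProtein:
    """Assign one of {refprot, novel_isoform, altprot} to a predicted protein."""
    exact = ref.exact_matches(p.sequence)
    if exact:
        # prefer an entry sharing a gene; exact duplicates at another locus
        # are still the same protein, with a cross-locus note
        shared = [e for e in exact if e[1] & p.genes]
        hit = (shared or exact)[0]
        note = "" if shared else "exact match to reference protein of a different gene"
        return ClassifiedProtein(
            record=p,
            cls=REFPROT,
            accession=hit[0],
            best_ref_hit=(hit[0], 1.0, 1.0),
            cross_locus_note=note,
        )
    best: tuple[float, str, float, float] | None = None
    for acc, _genes, seq in ref.entries_for_genes(p.genes):
        score, identity, coverage = local_identity(p.sequence, seq)
        if best is None or score > best[0]:
            best = (score, acc, identity, coverage)
    if best is not None:
        _, acc, identity, coverage = best
        if identity >= id_threshold and coverage >= cov_threshold:
            return ClassifiedProtein(
                record=p,
                cls=NOVEL_ISOFORM,
                best_ref_hit=(acc, identity, coverage),
            )
        return ClassifiedProtein(
            record=p, cls=ALTPROT, best_ref_hit=(acc, identity, coverage)
        )
    return ClassifiedProtein(record=p, cls=ALTPROT)


def mint_accessions(proteins: list[ClassifiedProtein]) -> list[ClassifiedProtein]:
    """Assign II_/IP_ numbers in deterministic genomic order.

    The same input set yields the same accessions regardless of input order.
    """
    ordered = sorted(proteins, key=lambda cp: cp.record.sort_key)
    ii = ip = 0
    for cp in ordered:
        if cp.cls == NOVEL_ISOFORM:
            ii += 1
            cp.accession = f"II_{ii}"
        elif cp.cls == ALTPROT:
            ip += 1
            cp.accession = f"IP_{ip}"
        for orf in cp.record.orfs:
            orf.accession = cp.accession
    return ordered


def promote_to_reference(
    current: list[ClassifiedProtein], new_ref: ReferenceProteome
) -> Counter:
    """Reclassify proteins now present in a newer reference proteome.

    Mutates classes in place and returns transition counts, e.g.
    ``{"altprot->refprot": 2}``.
    """
    report: Counter = Counter()
    for cp in current:
        if cp.cls == REFPROT:
            continue
        exact = new_ref.exact_matches(cp.sequence)
        if exact:
            report[f"{cp.cls}->{REFPROT}"] += 1
            cp.cls = REFPROT
            cp.accession = exact[0][0]
            cp.best_ref_hit = (exact[0][0], 1.0, 1.0)
    return report
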