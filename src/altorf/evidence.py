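"""Expression-evidence aggregation: target-decoy FDR, peptide uniqueness,
detection calls and multi-coding transcript flags.

The detection rule: a protein is called detected with at least 2 unique MS
peptides, or 1 unique peptide plus at least one ribo-seq detection. A
transcript encoding ≥2 detected proteins is flagged multi-coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ALTPROT, NOVEL_ISOFORM, REFPROT, ClassifiedProtein, ReferenceProteome

DEFAULT_FDR_MAX = 0.0001  # PSM-level FDR < 0.01%


@dataclass(frozen=True)
class PsmRecord:
    peptide: str
    score: float
    is_decoy: bool
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")


def fdr_filter(psms: list[PsmRecord], fdr_max: float = DEFAULT_FDR_MAX) -> list[PsmRecord]:
    """Accept target PSMs at the most permissive score threshold with
    target-decoy FDR (#decoys/#targets among accepted) below ``fdr_max``.

    Decoys are never returned; an all-decoy input yields an empty result.
    """
    if not psms:
        return []
    ranked = sorted(psms, key=lambda p: -p.score)
    best_cut = None  # number of top-ranked PSMs accepted
    targets = decoys = 0
    for i, psm in enumerate(ranked):
        if psm.is_decoy:
            decoys += 1
        else:
            targets += 1
        # a threshold must fall between distinct scores
        if i + 1 < len(ranked) and ranked[i + 1].score == psm.score:
            continue
        if targets > 0 and decoys / targets < fdr_max:
            best_cut = i + 1
    if best_cut is None:
        return []
    return [p for p in ranked[:best_cut] if not p.is_decoy]


def map_peptides(
    peptides: list[str],
    proteins: list[ClassifiedProtein],
    references: ReferenceProteome,
    il_equivalent: bool = True,
) -> dict[str, int]:
    """Count unique peptides per protein accession.

    A peptide is unique evidence for an AltProt or novel isoform iff it
    occurs as a substring of exactly one predicted protein and of no
    reference proteome sequence. I and L are treated as equivalent by
    default (indistinguishable by mass). For reference-class proteins the
    peptide may of course occur in the reference proteome, but only within
    entries of that same sequence.
    """
    collapse = (lambda s: s.replace("L", "I")) if il_equivalent else (lambda s: s)
    prot_seqs = [(cp, collapse(cp.sequence)) for cp in proteins]
    ref_seqs = [collapse(seq) for _, _, seq in references.entries]
    counts: dict[str, int] = {cp.accession: 0 for cp in proteins}
    for peptide in peptides:
        pep = collapse(peptide)
        hits = [cp for cp, seq in prot_seqs if pep in seq]
        if len(hits) != 1:
            continue
        cp = hits[0]
        if cp.cls in (ALTPROT, NOVEL_ISOFORM):
            if any(pep in rseq for rseq in ref_seqs):
                continue
        else:  # refprot: occurrence in a *different* reference sequence disqualifies
            own = collapse(cp.sequence)
            if any(pep in rseq for rseq in ref_seqs if rseq != own):
                continue
        counts[cp.accession] += 1
    return counts


@dataclass
class EvidenceSummary:
    accession: str
    unique_peptides: int
    riboseq_detections: int
    detected: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.unique_peptides < 0 or self.riboseq_detections < 0:
            raise ValueError("evidence counts must be non-negative")
        self.detected = self.unique_peptides >= 2 or (
            self.unique_peptides >= 1 and self.riboseq_detections >= 1
        )


def evidence_call(
    accession: str, unique_peptides: int, riboseq_detections: int
) -> EvidenceSummary:
    """Detection call: ≥2 unique peptides, or 1 peptide + ≥1 ribo-seq detection."""
    return EvidenceSummary(accession, unique_peptides, riboseq_detections)


@dataclass
class MultiCodingFlag:
    transcript_id: str
    coding_proteins: list[str]
    is_multicoding: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_multicoding = len(self.coding_proteins) >= 2


def flag_multicoding(
    transcript_proteins: dict[str, list[str]], evidence: dict[str, EvidenceSummary]
) -> dict[str, MultiCodingFlag]:
    """Flag transcripts encoding ≥2 detected proteins.

    ``transcript_proteins`` maps transcript_id → accessions of all proteins
    its ORFs encode.
    """
    flags = {}
    for tx_id, accessions in transcript_proteins.items():
        detected = sorted(
            {a for a in accessions if a in evidence and evidence[a].detected}
        )
        flags[tx_id] = MultiCodingFlag(tx_id, detected)
    return flags
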