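"""Exhaustive multi-frame ORF enumeration and protein deduplication.

Every transcript is scanned in all three reading frames regardless of its
annotated biotype. An ORF runs from a start codon (ATG by default) to the
first in-frame stop; within one (frame, stop) pair only the most 5′ start
defines the reported ORF. The minimum size is 30 codons *including* the stop
codon, so the shortest reported protein is 29 residues. No upper size bound
is applied. A codon containing an unknown base (N) aborts the ORF in
progress rather than fabricating an amino acid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import Transcript

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = ("ATG",)
DEFAULT_MIN_CODONS = 30

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    The trailing stop codon (if present) is dropped. An internal stop or a
    non-ACGT character raises ValueError.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    residues = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at position {3 * i}")
        if aa == "*":
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon {codon!r} at position {3 * i}")
            break
        residues.append(aa)
    return "".join(residues)


@dataclass
class OrfCandidate:
    """One predicted ORF on one transcript."""

    transcript_id: str
    frame: int
    t_start: int
    t_end: int  # one past the last base of the stop codon
    codon_count: int  # stop codon included
    genomic_blocks: list[tuple[str, int, int, str]]
    protein: str
    accession: str = ""  # filled after classification

    def __post_init__(self) -> None:
        if self.t_end - self.t_start != 3 * self.codon_count:
            raise ValueError("ORF span does not match codon count")
        if len(self.protein) != self.codon_count - 1:
            raise ValueError("protein length inconsistent with codon count")

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}:{self.t_start}-{self.t_end}"


def enumerate_orfs(
    t: Transcript,
    seq: str,
    min_codons: int = DEFAULT_MIN_CODONS,
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS,
    all_starts: bool = False,
) -> list[OrfCandidate]:
    """Enumerate qualifying ORFs in all three frames of a spliced sequence.

    With ``all_starts`` every in-frame start sharing a stop is reported as a
    separate (nested) ORF; by default only the most 5′ start per stop is.
    """
    starts = frozenset(start_codons)
    found: list[tuple[int, int, int]] = []  # (frame, t_start, t_end)
    for frame in range(3):
        open_starts: list[int] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                open_starts = []  # ambiguous codon aborts any ORF in progress
                continue
            if codon in STOP_CODONS:
                for s in open_starts if all_starts else open_starts[:1]:
                    n_codons = (pos + 3 - s) // 3
                    if n_codons >= min_codons:
                        found.append((frame, s, pos + 3))
                open_starts = []
            elif codon in starts:
                open_starts.append(pos)
    orfs = []
    for frame, t_start, t_end in sorted(found, key=lambda x: (x[1], x[2])):
        orfs.append(
            OrfCandidate(
                transcript_id=t.transcript_id,
                frame=frame,
                t_start=t_start,
                t_end=t_end,
                codon_count=(t_end - t_start) // 3,
                genomic_blocks=t.genomic_blocks(t_start, t_end),
                protein=translate(seq[t_start:t_end]),
            )
        )
    return orfs


@dataclass
class ProteinRecord:
    """A deduplicated predicted protein with all of its encoding loci."""

    sequence: str
    orfs: list[OrfCandidate] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    transcripts: set[str] = field(default_factory=set)
    multi_locus: bool = False

    @property
    def sort_key(self) -> tuple:
        first = min((o.genomic_blocks[0][0], o.genomic_blocks[0][1]) for o in self.orfs)
        return (first[0], first[1], self.sequence)


def deduplicate(
    orfs: list[OrfCandidate], transcripts: dict[str, Transcript]
) -> list[ProteinRecord]:
    """Collapse ORFs into one record per distinct protein sequence.

    Records are returned in deterministic order (first genomic block, then
    sequence); identical proteins encoded by >1 gene are flagged multi-locus.
    """
    by_seq: dict[str, ProteinRecord] = {}
    for orf in orfs:
        rec = by_seq.setdefault(orf.protein, ProteinRecord(sequence=orf.protein))
        rec.orfs.append(orf)
        rec.transcripts.add(orf.transcript_id)
        rec.genes.add(transcripts[orf.transcript_id].gene_id)
    records = sorted(by_seq.values(), key=lambda r: r.sort_key)
    for rec in records:
        rec.orfs.sort(key=lambda o: (o.genomic_blocks[0][0], o.genomic_blocks[0][1], o.transcript_id))
        rec.multi_locus = len(rec.genes) > 1
    return records
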