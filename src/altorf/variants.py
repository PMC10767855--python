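"""Per-ORF genomic variant consequence annotation.

One genomic variant yields an independent consequence call for *every* ORF
of every overlapping transcript — including frame-overlapping ORFs, where
the same nucleotide change can be synonymous in one frame and missense in
another. Consequences are obtained by applying the edit to the spliced
transcript sequence and re-translating the ORF from its start codon.

Impact classes follow the conventional variant-annotation mapping:
synonymous→low; missense and in-frame indels→moderate; stop/start loss,
stop gain and frameshift→high; everything outside an ORF→modifier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from cyvcf2 import VCF

from .models import GenomeSequences, Transcript, _strip_chr, revcomp
from .orfs import STOP_CODONS, OrfCandidate

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"
FRAMESHIFT = "frameshift"
INFRAME_INSERTION = "inframe_insertion"
INFRAME_DELETION = "inframe_deletion"
NON_ORF = "non_orf"

IMPACT_OF = {
    SYNONYMOUS: "low",
    MISSENSE: "moderate",
    INFRAME_INSERTION: "moderate",
    INFRAME_DELETION: "moderate",
    STOP_GAINED: "high",
    STOP_LOST: "high",
    START_LOST: "high",
    FRAMESHIFT: "high",
    NON_ORF: "modifier",
}

IMPACT_RANK = {"high": 3, "moderate": 2, "low": 1, "modifier": 0}


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant; ``pos`` is internal 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("empty REF allele")

    @property
    def key(self) -> str:
        return self.id if self.id not in (".", "") else f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"


def normalize_variant(v: VariantRecord, genome: GenomeSequences) -> VariantRecord:
    """Trim shared suffix/prefix bases and left-align against the genome."""
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-align a pure indel while the flanking base allows it
    if len(ref) != len(alt) and (len(ref) == 1 or len(alt) == 1):
        while pos > 0 and ref[-1] == alt[-1]:
            prev = genome.fetch(v.chrom, pos - 1, pos)
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
    return VariantRecord(v.chrom, pos, ref, alt, v.id)


def read_vcf(path: str, genome: GenomeSequences) -> list[VariantRecord]:
    """Read a VCF (4.x), split multi-allelic sites, verify REF concordance."""
    records = []
    for var in VCF(str(path)):
        pos = var.POS - 1  # 1-based → internal 0-based
        ref = var.REF.upper()
        observed = genome.fetch(var.CHROM, pos, pos + len(ref))
        if observed != ref:
            raise ValueError(
                f"REF mismatch at {var.CHROM}:{var.POS}: VCF says {ref!r}, genome has {observed!r}"
            )
        for alt in var.ALT:
            records.append(
                normalize_variant(
                    VariantRecord(var.CHROM, pos, ref, alt.upper(), var.ID or "."), genome
                )
            )
    return records


@dataclass(frozen=True)
class ConsequenceCall:
    variant_key: str
    accession: str
    orf_id: str
    transcript_id: str
    consequence: str
    impact: str
    ref_excerpt: str = ""
    alt_excerpt: str = ""
    note: str = ""


def _transcript_edit(
    v: VariantRecord, t: Transcript
) -> tuple[int, str, str] | None:
    """Project a genomic edit into transcript space.

    Returns (t_pos, ref_t, alt_t) replacing t_seq[t_pos : t_pos+len(ref_t)],
    or None when the variant does not lie fully within one exon.
    """
    g_positions = range(v.pos, v.pos + len(v.ref))
    if not all(t.contains_genomic(g) for g in g_positions):
        return None
    t_positions = [t.to_transcript(g) for g in g_positions]
    lo, hi = min(t_positions), max(t_positions)
    if hi - lo + 1 != len(v.ref):  # ref spans a splice junction in transcript space
        return None
    if t.strand == "+":
        return lo, v.ref, v.alt
    return lo, revcomp(v.ref), revcomp(v.alt)


def _translate_from(seq: str, start: int) -> tuple[str, bool]:
    """Translate codons from ``start`` to the first stop; returns
    (protein, stop_found)."""
    residues = []
    from .orfs import _CODON_TABLE

    for pos in range(start, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            break
        if aa == "*":
            return "".join(residues), True
        residues.append(aa)
    return "".join(residues), False


def _call_for_orf(
    v: VariantRecord,
    orf: OrfCandidate,
    t: Transcript,
    t_seq: str,
    start_codons: tuple[str, ...] = ("ATG",),
) -> ConsequenceCall:
    edit = _transcript_edit(v, t)
    if edit is None:
        return ConsequenceCall(
            v.key, orf.accession, orf.orf_id, t.transcript_id, NON_ORF,
            IMPACT_OF[NON_ORF], note="variant spans an exon-intron boundary",
        )
    t_pos, ref_t, alt_t = edit
    edit_lo, edit_hi = t_pos, t_pos + len(ref_t)
    if edit_hi <= orf.t_start or edit_lo >= orf.t_end:
        return ConsequenceCall(
            v.key, orf.accession, orf.orf_id, t.transcript_id, NON_ORF, IMPACT_OF[NON_ORF]
        )
    assert t_seq[edit_lo:edit_hi] == ref_t
    mutated = t_seq[:edit_lo] + alt_t + t_seq[edit_hi:]
    delta = len(alt_t) - len(ref_t)

    # start codon disrupted?
    if edit_lo < orf.t_start + 3 and mutated[orf.t_start : orf.t_start + 3] not in start_codons:
        cons = START_LOST
        return ConsequenceCall(
            v.key, orf.accession, orf.orf_id, t.transcript_id, cons, IMPACT_OF[cons],
            ref_excerpt=orf.protein[:5], alt_excerpt="",
        )
    if delta % 3 != 0:
        cons = FRAMESHIFT
        return ConsequenceCall(
            v.key, orf.accession, orf.orf_id, t.transcript_id, cons, IMPACT_OF[cons]
        )
    new_protein, stop_found = _translate_from(mutated, orf.t_start)
    old_protein = orf.protein
    note = ""
    if delta > 0:
        cons = INFRAME_INSERTION
    elif delta < 0:
        cons = INFRAME_DELETION
    elif new_protein == old_protein:
        cons = SYNONYMOUS
    elif len(new_protein) < len(old_protein):
        cons = STOP_GAINED
    elif len(new_protein) > len(old_protein):
        cons = STOP_LOST
        if not stop_found:
            note = "no new in-frame stop before transcript 3' end"
    else:
        cons = MISSENSE
    return ConsequenceCall(
        v.key, orf.accession, orf.orf_id, t.transcript_id, cons, IMPACT_OF[cons],
        ref_excerpt=old_protein[:10], alt_excerpt=new_protein[:10], note=note,
    )


def annotate_variant(
    v: VariantRecord,
    orfs_by_transcript: dict[str, list[OrfCandidate]],
    transcripts: dict[str, Transcript],
    spliced: dict[str, str],
    start_codons: tuple[str, ...] = ("ATG",),
) -> list[ConsequenceCall]:
    """One independent ConsequenceCall per ORF of each overlapping transcript."""
    calls = []
    for tx_id, orfs in orfs_by_transcript.items():
        t = transcripts[tx_id]
        if _strip_chr(t.chrom) != _strip_chr(v.chrom):
            continue
        if v.pos + len(v.ref) <= t.genomic_start or v.pos >= t.genomic_end:
            continue
        for orf in orfs:
            calls.append(_call_for_orf(v, orf, t, spliced[tx_id], start_codons))
    return calls


def mutated_protein_sequence(
    v: VariantRecord,
    orf: OrfCandidate,
    t: Transcript,
    t_seq: str,
    start_codons: tuple[str, ...] = ("ATG",),
) -> str | None:
    """Full protein produced by the ORF after applying the variant.

    Returns None for non-coding placements (outside the ORF, boundary
    spanning, or start loss with no translation).
    """
    edit = _transcript_edit(v, t)
    if edit is None:
        return None
    t_pos, ref_t, alt_t = edit
    if t_pos + len(ref_t) <= orf.t_start or t_pos >= orf.t_end:
        return None
    mutated = t_seq[:t_pos] + alt_t + t_seq[t_pos + len(ref_t):]
    if mutated[orf.t_start : orf.t_start + 3] not in start_codons:
        return None
    protein, _ = _translate_from(mutated, orf.t_start)
    return protein or None


def summarize_impacts(
    calls: list[ConsequenceCall], classes: dict[str, str] | None = None
) -> tuple[dict[str, str], Counter]:
    """Worst impact per variant and a per-(protein-class, impact) tally.

    ``classes`` maps ORF accession → protein class; calls with unknown
    accessions tally under class "unclassified".
    """
    worst: dict[str, str] = {}
    tally: Counter = Counter()
    for call in calls:
        cur = worst.get(call.variant_key)
        if cur is None or IMPACT_RANK[call.impact] > IMPACT_RANK[cur]:
            worst[call.variant_key] = call.impact
        cls = (classes or {}).get(call.accession, "unclassified")
        tally[(cls, call.impact)] += 1
    return worst, tally
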