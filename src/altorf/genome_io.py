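"""Readers for genome FASTA and transcript annotation (GFF3/GTF).

Both annotation dialects are parsed through gffutils into the same
:class:`~altorf.models.Transcript` representation, so downstream code never
sees the dialect. Coordinates are converted from 1-based inclusive to the
internal 0-based half-open convention here and nowhere else.
"""

from __future__ import annotations

import warnings

import gffutils
from Bio import SeqIO

from .models import Exon, GenomeSequences, Transcript, revcomp


def read_genome(path: str) -> GenomeSequences:
    """Read a genome FASTA; uppercases and converts U→T.

    Raises on duplicate record names and on an empty file.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA record name {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequences(sequences)


_TRANSCRIPT_TYPES = {"transcript", "mRNA", "lnc_RNA", "ncRNA", "pseudogenic_transcript"}


def _attr(feature, *keys: str, default: str = "") -> str:
    for key in keys:
        if key in feature.attributes:
            return feature.attributes[key][0]
    return default


def read_annotation(path: str, source_label: str) -> list[Transcript]:
    """Parse a GFF3 or GTF file into strand-resolved transcript models.

    Exons lacking a resolvable parent transcript are skipped with a warning;
    transcripts declaring no exon features get one exon spanning the
    transcript feature.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    # collect transcript features and their exons
    tx_feats: dict[str, gffutils.Feature] = {}
    for ftype in _TRANSCRIPT_TYPES:
        for f in db.features_of_type(ftype):
            tx_id = _attr(f, "transcript_id", "ID")
            if tx_id:
                tx_feats[tx_id] = f
    exons_by_tx: dict[str, list[gffutils.Feature]] = {t: [] for t in tx_feats}
    for f in db.features_of_type("exon"):
        parent = _attr(f, "transcript_id", "Parent")
        if parent not in exons_by_tx:
            warnings.warn(f"exon at {f.seqid}:{f.start}-{f.end} has no parent transcript; skipped")
            continue
        exons_by_tx[parent].append(f)

    transcripts = []
    for tx_id, tf in tx_feats.items():
        feats = exons_by_tx[tx_id] or [tf]
        chroms = {f.seqid for f in feats}
        if len(chroms) > 1:
            raise ValueError(f"transcript {tx_id} spans multiple chromosomes {chroms}")
        strand = tf.strand if tf.strand in ("+", "-") else "+"
        exons = [
            Exon(f.seqid, f.start - 1, f.end, strand)  # 1-based inclusive → 0-based half-open
            for f in feats
        ]
        exons.sort(key=lambda e: e.start, reverse=strand == "-")
        transcripts.append(
            Transcript(
                transcript_id=tx_id,
                gene_id=_attr(tf, "gene_id", "geneID", default=tx_id),
                gene_name=_attr(tf, "gene_name", "Name"),
                biotype=_attr(tf, "transcript_biotype", "biotype", "gene_biotype"),
                source=source_label,
                strand=strand,
                exons=exons,
            )
        )
    transcripts.sort(key=lambda t: (t.chrom, t.genomic_start, t.transcript_id))
    return transcripts


def merge_annotations(
    primary: list[Transcript], secondary: list[Transcript]
) -> list[Transcript]:
    """Pool transcripts from two annotation sources under merged genes.

    Genes from different sources are considered the same gene when their
    gene_name matches (case-insensitive) or their genomic spans overlap on
    the same strand; the primary source's gene_id wins for merged genes.
    """
    spans: dict[str, tuple[str, str, int, int, str]] = {}
    for t in primary:
        chrom, strand = t.chrom, t.strand
        if t.gene_id in spans:
            _, _, lo, hi, name = spans[t.gene_id]
            spans[t.gene_id] = (chrom, strand, min(lo, t.genomic_start), max(hi, t.genomic_end), name)
        else:
            spans[t.gene_id] = (chrom, strand, t.genomic_start, t.genomic_end, t.gene_name)

    merged = list(primary)
    for t in secondary:
        canonical = None
        for gid, (chrom, strand, lo, hi, name) in spans.items():
            same_name = t.gene_name and name and t.gene_name.lower() == name.lower()
            overlaps = (
                chrom == t.chrom
                and strand == t.strand
                and t.genomic_start < hi
                and lo < t.genomic_end
            )
            if same_name or overlaps:
                canonical = gid
                break
        if canonical is not None:
            t = Transcript(
                transcript_id=t.transcript_id,
                gene_id=canonical,
                gene_name=t.gene_name,
                biotype=t.biotype,
                source=t.source,
                strand=t.strand,
                exons=t.exons,
            )
        merged.append(t)
    merged.sort(key=lambda t: (t.chrom, t.genomic_start, t.transcript_id))
    return merged


def spliced_sequence(t: Transcript, genome: GenomeSequences) -> str:
    """Spliced (mature) transcript sequence, 5′→3′."""
    parts = []
    for exon in t.exons:
        chunk = genome.fetch(exon.chrom, exon.start, exon.end)
        parts.append(revcomp(chunk) if t.strand == "-" else chunk)
    return "".join(parts)
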