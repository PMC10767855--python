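"""Writers for the downloadable products: BED12, protein FASTA, TSV tables."""

from __future__ import annotations

from .classify import ClassifiedProtein
from .evidence import EvidenceSummary
from .orfs import OrfCandidate


def write_orf_bed(orfs: list[OrfCandidate], path: str, metadata: list[str] | None = None) -> None:
    """BED12, one line per ORF; blocks are the exon-intersected ORF segments.

    Native 0-based half-open; thickStart/thickEnd span the whole ORF.
    """
    with open(path, "w") as fh:
        for line in metadata or []:
            fh.write(f"#{line}\n")
        for orf in orfs:
            blocks = sorted(orf.genomic_blocks, key=lambda b: b[1])
            chrom = blocks[0][0]
            strand = blocks[0][3]
            chrom_start = blocks[0][1]
            chrom_end = blocks[-1][2]
            sizes = ",".join(str(e - s) for _, s, e, _ in blocks)
            starts = ",".join(str(s - chrom_start) for _, s, _, _ in blocks)
            name = orf.accession or orf.orf_id
            fh.write(
                f"{chrom}\t{chrom_start}\t{chrom_end}\t{name}\t0\t{strand}\t"
                f"{chrom_start}\t{chrom_end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def read_bed_blocks(path: str) -> list[tuple[str, list[tuple[str, int, int, str]]]]:
    """Parse a BED12 file back into (name, genomic blocks) — round-trip check."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                (chrom, chrom_start + st, chrom_start + st + sz, strand)
                for st, sz in zip(starts, sizes)
            ]
            out.append((name, blocks))
    return out


def write_protein_fasta(
    proteins: list[ClassifiedProtein], path: str, metadata: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in metadata or []:
            fh.write(f";{line}\n")
        for cp in proteins:
            genes = ",".join(sorted(cp.record.genes))
            txs = ",".join(sorted(cp.record.transcripts))
            fh.write(f">{cp.accession} class={cp.cls} GN={genes} TX={txs}\n")
            for i in range(0, len(cp.sequence), 60):
                fh.write(cp.sequence[i : i + 60] + "\n")


ANNOTATION_COLUMNS = [
    "accession", "class", "gene", "gene_name", "transcripts", "codon_count",
    "protein_length", "best_ref_hit", "identity", "coverage", "multi_locus",
    "unique_peptides", "riboseq_detections", "detected",
]


def write_annotation_tsv(
    proteins: list[ClassifiedProtein],
    path: str,
    evidence: dict[str, EvidenceSummary] | None = None,
    gene_names: dict[str, str] | None = None,
    metadata: list[str] | None = None,
) -> None:
    """One row per predicted protein, with classification and evidence fields."""
    evidence = evidence or {}
    gene_names = gene_names or {}
    with open(path, "w") as fh:
        for line in metadata or []:
            fh.write(f"#{line}\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for cp in proteins:
            ev = evidence.get(cp.accession)
            hit_acc, ident, cov = ("-", "", "")
            if cp.best_ref_hit:
                hit_acc = cp.best_ref_hit[0]
                ident = f"{cp.best_ref_hit[1]:.4f}"
                cov = f"{cp.best_ref_hit[2]:.4f}"
            genes = ",".join(sorted(cp.record.genes))
            row = [
                cp.accession,
                cp.cls,
                genes,
                ",".join(sorted({gene_names.get(g, "") for g in cp.record.genes} - {""})),
                ",".join(sorted(cp.record.transcripts)),
                str(cp.record.orfs[0].codon_count),
                str(len(cp.sequence)),
                hit_acc,
                ident,
                cov,
                "1" if cp.record.multi_locus else "0",
                str(ev.unique_peptides) if ev else "",
                str(ev.riboseq_detections) if ev else "",
                ("1" if ev.detected else "0") if ev else "",
            ]
            fh.write("\t".join(row) + "\n")
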