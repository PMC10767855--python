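"""Core domain types: exons, spliced transcripts and the transcript↔genome map.

All internal coordinates are 0-based half-open. GFF3/GTF (1-based inclusive)
and VCF (1-based) are converted at the parser boundary; BED output is native
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Exon:
    """A genomic exon block, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid exon interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


class GenomeSequences:
    """Chromosome name → uppercase nucleotide sequence (A/C/G/T/N only).

    Lookup tolerates a "chr" prefix mismatch between annotation and FASTA;
    output preserves names as seen in the FASTA.
    """

    def __init__(self, sequences: dict[str, str]):
        self.sequences: dict[str, str] = {}
        self._by_norm: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self.sequences:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper().replace("U", "T")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"non-nucleotide characters in {name!r}: {sorted(bad)}")
            self.sequences[name] = seq
            norm = _strip_chr(name)
            if norm in self._by_norm:
                raise ValueError(f"chromosome names {name!r} and {self._by_norm[norm]!r} collide")
            self._by_norm[norm] = name

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences or _strip_chr(chrom) in self._by_norm

    def resolve(self, chrom: str) -> str:
        """Map an annotation chromosome name to the FASTA name."""
        if chrom in self.sequences:
            return chrom
        norm = _strip_chr(chrom)
        if norm in self._by_norm:
            return self._by_norm[norm]
        raise KeyError(f"chromosome {chrom!r} not in genome")

    def fetch(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        seq = self.sequences[self.resolve(chrom)]
        if start is None:
            return seq
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"slice [{start},{end}) outside {chrom} (length {len(seq)})")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[self.resolve(chrom)])

    def names(self) -> list[str]:
        return list(self.sequences)


@dataclass
class Transcript:
    """Spliced transcript model with a bidirectional coordinate map.

    ``exons`` are ordered 5′→3′ in transcript orientation: ascending genomic
    start on the plus strand, descending on the minus strand.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    source: str
    strand: str
    exons: list[Exon]
    _offsets: list[int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"{self.transcript_id}: exons span multiple chromosomes {chroms}")
        if any(e.strand != self.strand for e in self.exons):
            raise ValueError(f"{self.transcript_id}: exon strand mismatch")
        ordered = sorted(self.exons, key=lambda e: e.start, reverse=self.strand == "-")
        if [
            (e.start, e.end) for e in ordered
        ] != [(e.start, e.end) for e in self.exons]:
            raise ValueError(f"{self.transcript_id}: exons not ordered 5'->3'")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        offsets, cum = [], 0
        for e in self.exons:
            offsets.append(cum)
            cum += e.length
        self._offsets = offsets

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return self._offsets[-1] + self.exons[-1].length

    @property
    def genomic_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e.end for e in self.exons)

    def to_genomic(self, t_pos: int) -> int:
        """Transcript offset → genomic position of that base."""
        if not (0 <= t_pos < self.spliced_length):
            raise ValueError(f"transcript offset {t_pos} out of range")
        for off, exon in zip(self._offsets, self.exons):
            if t_pos < off + exon.length:
                within = t_pos - off
                if self.strand == "+":
                    return exon.start + within
                return exon.end - 1 - within
        raise AssertionError("unreachable")

    def to_transcript(self, g_pos: int) -> int:
        """Genomic position → transcript offset; raises if intronic/outside."""
        for off, exon in zip(self._offsets, self.exons):
            if exon.start <= g_pos < exon.end:
                if self.strand == "+":
                    return off + (g_pos - exon.start)
                return off + (exon.end - 1 - g_pos)
        raise ValueError(
            f"genomic position {g_pos} not exonic in transcript {self.transcript_id}"
        )

    def contains_genomic(self, g_pos: int) -> bool:
        return any(e.start <= g_pos < e.end for e in self.exons)

    def genomic_blocks(self, t_start: int, t_end: int) -> list[tuple[str, int, int, str]]:
        """Genomic blocks covered by transcript interval [t_start, t_end).

        Blocks are returned in ascending genomic order (BED convention).
        """
        if not (0 <= t_start < t_end <= self.spliced_length):
            raise ValueError(f"interval [{t_start},{t_end}) out of range")
        blocks = []
        for off, exon in zip(self._offsets, self.exons):
            lo = max(t_start, off)
            hi = min(t_end, off + exon.length)
            if lo >= hi:
                continue
            if self.strand == "+":
                g_lo = exon.start + (lo - off)
                g_hi = exon.start + (hi - off)
            else:
                g_hi = exon.end - (lo - off)
                g_lo = exon.end - (hi - off)
            blocks.append((exon.chrom, g_lo, g_hi, self.strand))
        return sorted(blocks, key=lambda b: b[1])
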