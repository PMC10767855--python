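# altorf

Annotation toolkit for the **alternative ORFeome**: the open reading frames
that standard genome annotations miss because they sit in UTRs, overlap the
reference CDS in another reading frame, or live in RNAs labelled non-coding
(lncRNAs, pseudogene transcripts).

`altorf` is written for proteogenomics practitioners who need, at any scale
from a mini-genome fixture to a full annotation set:

1. **Exhaustive ORF prediction** — every transcript is scanned in all three
   frames regardless of biotype. An ORF runs from a start codon (ATG by
   default) to the first in-frame stop; within one (frame, stop) pair only
   the most 5′ start is reported. The minimum size is **30 codons including
   the stop** (shortest protein: 29 aa); there is no upper bound.
2. **Three-class protein classification** — each deduplicated protein is a
   *reference protein* (exact match to the reference proteome), a *novel
   isoform* (`II_` accessions: substantial similarity — Smith–Waterman
   BLOSUM62, identity ≥ 0.8 over ≥ 0.5 of the shorter sequence — to a
   reference protein of the **same gene**), or an *alternative protein*
   (`IP_` accessions) otherwise.
3. **Expression evidence** — target-decoy FDR filtering of PSMs (default
   FDR < 0.01%), peptide-uniqueness mapping (I/L-equivalent, checked
   against the reference proteomes), and the detection rule
   *detected ⇔ ≥2 unique peptides, or 1 peptide + ≥1 ribo-seq detection*;
   transcripts encoding ≥2 detected proteins are flagged **multi-coding**.
4. **Functional post-processing** — intrinsically disordered regions as
   runs of **≥29 consecutive disordered residues**; SLiMs with any ordered
   residue filtered out; pLDDT confidence bins (>90 very high, 70–90 high,
   50–70 medium, ≤50 very low); structure-predictor routing (alignment-free
   predictor when the MSA holds <30 sequences).
5. **Multi-ORF variant effects** — each genomic variant gets an independent
   consequence call for *every* ORF of every overlapping transcript, so a
   single SNV can be synonymous in one frame and missense in an overlapping
   frame. Impacts: synonymous→low; missense/in-frame indel→moderate;
   stop gain/loss, start loss, frameshift→high; non-coding→modifier.
6. **Custom protein databases** — transcripts ranked by TPM (ties broken
   lexicographically) and admitted whole until the protein cap (default
   100 000) would be exceeded; include/exclude lists override the ranking;
   variant protein sequences are emitted next to their references.

A first-class synthetic fixture generator (`altorf fixtures`) builds a
deterministic mini-genome with planted ground truth for all of the above,
so the entire toolkit is testable offline.

## Worked example

```bash
altorf fixtures --seed 1 --n-genes 12 --out fx
altorf run \
  --genome fx/genome.fa --gff fx/annotation.gff3 \
  --ref-proteome fx/ref_proteome.fa \
  --psm fx/psms.tsv --ribo fx/ribo.tsv \
  --disorder fx/disorder.tsv --slims fx/slims.tsv --structure fx/structure.tsv \
  --expr fx/expression.tsv --vcf fx/variants.vcf --out-dir out
# INFO fixture written to fx (16 transcripts, 32 proteins)
# INFO pipeline complete: 32 proteins, 120 consequence calls
```

`out/annotation.tsv` (one row per protein; columns abridged):

```
accession  class          gene       transcripts              codon_count  unique_peptides  riboseq_detections  detected
REF00000   refprot        ENSG00000  ENST00000T1              70           0                2                   0
II_1       novel_isoform  ENSG00000  ENST00000T2              60           2                0                   1
IP_1       altprot        ENSG00000  ENST00000T1,ENST00000T2  31           2                1                   1
IP_2       altprot        ENSG00000  ENST00000T1,ENST00000T2  46           2                0                   1
```

`REF00000` has ribo-seq signal but no unique peptide, so it is not called
detected; `II_1` (two unique peptides) and `IP_1` (one peptide plus one
ribo-seq detection) are. `out/consequences.tsv` shows the frame-overlap
behaviour — the same SNV truncates the reference protein while substituting
one residue of the alternative protein encoded two frames away on the same
transcript:

```
variant  transcript   orf                  accession  class    consequence  impact
var2     ENST00000T1  ENST00000T1:225-435  REF00000   refprot  stop_gained  high
var2     ENST00000T1  ENST00000T1:253-346  IP_1       altprot  missense     moderate
```

Other products: `orfs.bed` (BED12, blocks are the exon-intersected ORF
segments), `proteins.fa`, `custom_db.fa` + manifest. Every output header
carries the tool version and a hash of the scientific configuration.

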