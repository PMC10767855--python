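# Methods

This note documents the models, rules and numerical choices behind
`altorf`, the assumptions they rest on, and what the synthetic test bed
does and does not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open. GFF3/GTF (1-based
inclusive) and VCF (1-based) are converted at their parsers; BED output is
native 0-based. Transcript models hold exons 5′→3′ in transcript
orientation; the transcript↔genome map is exact and bijective over the
spliced length, with positions decreasing along the genome for
minus-strand transcripts. Chromosome names are matched with the "chr"
prefix stripped and emitted as seen in the genome FASTA, since
Ensembl-style and RefSeq-style naming routinely disagree.

When two annotation sources are merged, genes are identified across
sources by case-insensitive gene-name match *or* genomic-span overlap on
the same strand, and the primary source's gene identifier wins. No
published join rule exists for this step; the heuristic is deliberately
permissive (pooling transcripts under one gene only broadens the set of
reference proteins a prediction is compared against) and is a design
choice of this package.

## ORF model

An ORF is a start codon followed by in-frame sense codons and a required
stop, at least **30 codons including the stop** (so predicted proteins are
≥29 aa); there is no maximum. All three frames of every transcript are
scanned and the annotated biotype is never consulted — lncRNAs and
pseudogene transcripts are treated exactly like mRNAs. Within one
(frame, stop) pair only the most 5′ start defines the reported ORF, which
keeps the ORFeome tractable; `all_starts=True` (CLI `--all-starts`)
reports nested in-frame starts as separate ORFs instead. The start-codon
set defaults to {ATG} and is configurable (`--start-codons`) because
near-cognate initiation is real but not part of the default model. A codon
containing N aborts the ORF in progress: no amino acid is ever fabricated
from an ambiguous base. ORFs are deduplicated by exact protein sequence;
one protein record keeps every encoding ORF, transcript and gene, and is
flagged multi-locus when more than one gene encodes it.

## Classification

Exact sequence match to any reference entry ⇒ reference protein, keeping
the source accession (an exact match under a *different* gene is still the
same protein and is annotated with a cross-locus note rather than given a
second accession). Otherwise the protein is aligned (Smith–Waterman,
BLOSUM62, gap open 11 / extend 1) against every reference protein of its
gene(s); identity ≥ 0.80 over an aligned region covering ≥ 0.50 of the
shorter sequence ⇒ novel isoform, else alternative protein. The similarity
thresholds operationalise a criterion that is stated only qualitatively in
the literature on which this tool is modelled; both are CLI flags and are
recorded in the output metadata, and classification against a *disjoint*
gene set can never produce a novel isoform regardless of similarity.
Accessions (`II_n`, `IP_n`) are minted in deterministic genomic order
(first genomic block, then sequence), so identical inputs give identical
accessions under any input permutation. `promote_to_reference` re-checks
non-reference proteins against a newer reference proteome and reports
transition counts.

## Evidence model

PSM filtering follows the classical target-decoy estimate: PSMs are ranked
by score and FDR = #decoys/#targets among those accepted; the filter
returns targets at the most permissive score threshold with FDR strictly
below the bound (default 0.0001, i.e. <0.01%, applied at the PSM level;
peptide-level telescoping is left to the caller by pre-aggregating). Ties
are handled by only cutting between distinct scores. Peptide uniqueness
treats I and L as equivalent (indistinguishable by mass; switchable): a
peptide supports an alternative protein or novel isoform only if it occurs
in exactly one predicted protein and in no reference sequence. Detection
requires ≥2 unique peptides, or 1 unique peptide plus ≥1 ribo-seq
detection; ribo-seq detections are consumed as per-protein counts from a
table — no read processing happens here. A transcript with ≥2 detected
proteins is multi-coding.

## Functional post-processing

Disorder profiles arrive as per-residue flags or propensities (binarized
at 0.5; a predictor's own binary calls are preferred when present). IDRs
are maximal runs of ≥29 consecutive disordered residues — 29 rather than
the more common 30 because the shortest predicted proteins are 29 aa. A
SLiM is retained only if every residue of its span is disordered. pLDDT
bins: >90 very high, (70,90] high, (50,70] medium, ≤50 very low. The
quoted cutpoints 90 and 70 come with strict inequalities whose boundary
membership is undecidable from prose, so boundary values are assigned to
the lower bin; the medium bin is a convention of this package. Predictor
routing sends proteins whose MSA holds fewer than 30 sequences (query
included) to the alignment-free predictor.

## Variant consequences

Each variant is normalized (shared-base trimming, left-alignment of pure
indels against the genome), projected into transcript space (strand-aware,
alleles reverse-complemented on minus strands), applied to the spliced
sequence, and the ORF is re-translated from its start. Decision order:
outside the ORF's blocks or spanning an exon–intron boundary ⇒ non_orf
(no splice-disruption model is attempted); start codon destroyed ⇒
start_lost; net length change not divisible by 3 ⇒ frameshift; otherwise
the new translation decides — identical ⇒ synonymous, longer/shorter by
in-frame indel ⇒ inframe insertion/deletion, earlier stop ⇒ stop_gained,
later stop ⇒ stop_lost (reading through to the next in-frame stop, with a
note when none exists before the transcript end), else missense. Every ORF
of every overlapping transcript is called independently; calls in
different frames are never collapsed. The consequence→impact table
(synonymous→low; missense and in-frame indels→moderate; stop/start events
and frameshift→high; non_orf→modifier) follows the convention shared by
mainstream variant annotators.

## Custom databases

Transcripts pass include/exclude lists and a TPM floor, are ranked by TPM
descending (ties lexicographic by transcript id for determinism), and are
admitted **whole** — all their not-yet-admitted proteins plus variant
isoforms — until the next transcript would push the entry count past the
cap (default 100 000). Whole-transcript admission makes the admitted
transcript list a prefix-monotone function of the cap. Variant sequences
are emitted only for moderate/high coding consequences (synonymous changes
add no sequence) and alongside the reference sequence with a suffixed
accession; emitting variant-only databases is possible by dropping the
reference entries downstream.

## Synthetic study conditions

The fixture generator builds, from one integer seed, a two-chromosome
mini-genome (default 75 genes cycling protein-coding / lncRNA /
pseudogene, random strands, 1–3 exons per transcript, introns 40–120 nt).
Coding genes carry a reference ORF of 70–110 codons (protein emitted into
the reference proteome), an upstream ORF (30–60 codons) in the 5′UTR, a
frame-overlapping ORF (30–33 codons) embedded at +1 inside the CDS, and a
second transcript with a 10-codon in-frame exon skip yielding a novel
isoform; non-coding genes carry two alternative ORFs each. Background
sequence is scrubbed of stray ATGs, and a repair loop checks the assembled
transcripts against the brute-force oracle scanner, mutating unprotected
bases (or applying synonymous substitutions within a singly-constrained
planted frame) until planted and discovered ORF sets coincide exactly;
planted alternative proteins are re-sampled if they approach the
novel-isoform similarity thresholds. Evidence, disorder, SLiM, structure
and expression tables follow fixed per-protein plans (detection scenarios
cycle through the truth table; IDR plants cycle run lengths 29/28/none,
giving ~25% planted prevalence per class); variants are planted
genomically per coding gene — a wobble synonymous SNV, an SNV in the
frame-overlap window chosen to diverge between frames, a 1-nt insertion,
a stop-loss SNV and a 3′UTR SNV, plus one multi-allelic intergenic site —
with expected consequences derived by the independent mutate→retranslate
oracle at planting time.

What the fixtures do **not** emulate: real codon usage and GC structure,
splice-site sequence, overlapping genes, sequencing noise, spectral data,
real disorder/structure predictor outputs, or annotation disagreements
between sources beyond the merge unit tests. Passing the suite therefore
demonstrates algorithmic correctness of the rules above, not calibration
on biological data; headline census numbers from genome-scale resources
are out of reach at this scale by design, and the acceptance measures are
property-based (oracle agreements, boundary sharpness, determinism)
rather than count reproduction.

## Numerical and engineering choices

Problem sizes in the default test/acceptance runs — 1000 random sequences
(90–3000 nt) for scanner agreement, 1000 random transcripts for coordinate
round trips, a 75-gene fixture (≈250 planted ORF instances, 200 proteins),
500 random PSM sets, 1000 disorder profiles and 500 random variants — were
chosen so the whole study re-runs in seconds on one CPU while exercising
every rule boundary. All randomness flows through a single seeded NumPy
generator per entry point; the acceptance script derives sub-seeds from
its `--seed`. Alignments use Biopython's PairwiseAligner; an independent
Gotoh dynamic-programming implementation with traceback lives in
`altorf.oracles` and is used only for cross-checks. The `--threads` flag
is accepted and recorded for interface stability but the implementation is
single-threaded; results are therefore trivially independent of the
thread count. Known limitations: no splice-disruption or phasing model, no
Kozak-context scoring, no ortholog/conservation analysis, and the
reference-promotion report covers exact sequence matches only.
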