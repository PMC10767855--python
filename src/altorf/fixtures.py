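"""Deterministic mini-genome fixture generator with recorded ground truth.

Builds, from a single integer seed, everything the pipeline consumes —
genome FASTA, GFF3 (+ GTF twin), reference proteome FASTA, PSM / ribo-seq /
disorder / SLiM / structure / expression tables and a VCF — alongside a
machine-readable truth record of every planted ORF, protein class, evidence
call, IDR, confidence bin and variant consequence.

Gene layout: genes cycle through three kinds. *Coding* genes carry a
reference ORF (protein emitted into the reference proteome), an upstream
ORF in the 5′UTR, a frame-overlapping ORF inside the CDS, and a second
transcript with a 10-codon in-frame exon-skip producing a novel isoform.
*lncRNA* and *pseudogene* genes carry two alternative ORFs each, so the
three protein classes and biotype-blind scanning are all exercised.

Background sequence is scrubbed of stray start codons so the planted ORF
set is exactly what an exhaustive scan finds; a repair loop verifies this
against the brute-force oracle and mutates unprotected bases (or applies
synonymous codon substitutions inside a planted frame) until generated
sequence and planted truth agree.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .oracles import (
    gotoh_local,
    oracle_orf_scan,
    oracle_project_edit,
    oracle_translate_codon,
    oracle_variant_consequence,
)

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon in _SENSE_CODONS:
    _aa = oracle_translate_codon(_codon)
    _SYNONYMS.setdefault(_aa, ())
    _SYNONYMS[_aa] += (_codon,)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class FixtureSpec:
    """Knobs of the synthetic study conditions (all defaults deliberate)."""

    seed: int = 1
    n_genes: int = 75
    ref_orf_codons: tuple[int, int] = (70, 110)
    alt_orf_codons: tuple[int, int] = (30, 60)
    overlap_orf_codons: tuple[int, int] = (30, 33)
    isoform_deletion_codons: int = 10
    exons_per_transcript: tuple[int, int] = (1, 3)
    intron_length: tuple[int, int] = (40, 120)
    utr_pad: tuple[int, int] = (20, 60)
    intergenic: tuple[int, int] = (60, 140)
    min_codons: int = 30
    idr_min_run: int = 29
    tpm_sigma: float = 1.2


# ---------------------------------------------------------------------------
# sequence helpers


def _scrub_atg(seq: list[str]) -> list[str]:
    for i in range(len(seq) - 2):
        if seq[i] == "A" and seq[i + 1] == "T" and seq[i + 2] == "G":
            seq[i + 2] = "C"
    return seq


def _rand_background(rng: np.random.Generator, n: int) -> str:
    seq = list(rng.choice(list("ACGT"), size=n))
    return "".join(_scrub_atg([str(b) for b in seq]))


def _rand_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n-2) sense codons + stop."""
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2))
    stop = str(rng.choice(_STOPS))
    return "ATG" + body + stop


def _protein_of(orf_nt: str) -> str:
    out = []
    for i in range(0, len(orf_nt) - 3, 3):
        out.append(oracle_translate_codon(orf_nt[i : i + 3]))
    return "".join(out)


def _pick_replacement(seq: list[str], b: int) -> str:
    """A base change at ``b`` that does not create a new ATG nearby."""
    for cand in "CGAT":
        if cand == seq[b]:
            continue
        old = seq[b]
        seq[b] = cand
        window = "".join(seq[max(0, b - 2) : b + 3])
        seq[b] = old
        if "ATG" not in window:
            return cand
    return "C"


# ---------------------------------------------------------------------------
# per-gene construction


@dataclass
class _PlantedOrf:
    label: str  # refORF | uORF | overlapORF | altORF1 | altORF2
    t_start: int
    t_end: int
    protein: str = ""


@dataclass
class _Gene:
    index: int
    kind: str  # coding | lncRNA | pseudogene
    gene_id: str = ""
    gene_name: str = ""
    seq: str = ""  # spliced sequence of the primary transcript
    orfs: list[_PlantedOrf] = field(default_factory=list)
    deletion: tuple[int, int] | None = None  # exon-skip interval (T1 coords)
    cds_span: tuple[int, int] | None = None
    overlap_span: tuple[int, int] | None = None
    strand: str = "+"
    chrom: str = ""
    # filled at placement
    t1_gpos: list[int] = field(default_factory=list)
    t2_gpos: list[int] = field(default_factory=list)


def _repair(
    gene: _Gene, spec: FixtureSpec, rng: np.random.Generator
) -> bool:
    """Mutate the gene sequence until the oracle finds exactly the planted ORFs.

    Returns False when repair is impossible without touching a doubly
    constrained region (caller regenerates the gene).
    """
    seq = list(gene.seq)
    planted1 = {(o.t_start, o.t_end) for o in gene.orfs}
    spans = [(o.t_start, o.t_end) for o in gene.orfs]
    protected = set()
    for s, e in spans:
        protected.update(range(s, e))
    d = gene.deletion

    for _ in range(120):
        s_str = "".join(seq)
        extras: list[tuple[int, ...]] = []  # T1 base positions of the start codon
        found1 = {(s, e) for _, s, e, _ in oracle_orf_scan(s_str, spec.min_codons)}
        if planted1 - found1:
            return False
        extras.extend((s, s + 1, s + 2) for s, _ in sorted(found1 - planted1))
        if d is not None:
            d0, d1 = d
            shift = d1 - d0
            t2 = s_str[:d0] + s_str[d1:]
            planted2 = set()
            for o in gene.orfs:
                s2 = o.t_start if o.t_start < d0 else o.t_start - shift
                if o.label == "refORF":
                    e2 = o.t_end - shift
                else:
                    e2 = o.t_end if o.t_end <= d0 else o.t_end - shift
                planted2.add((s2, e2))
            found2 = {(s, e) for _, s, e, _ in oracle_orf_scan(t2, spec.min_codons)}
            if planted2 - found2:
                return False
            to_t1 = lambda b: b if b < d0 else b + shift
            for s2, _e2 in sorted(found2 - planted2):
                extras.append(tuple(to_t1(b) for b in (s2, s2 + 1, s2 + 2)))
        if not extras:
            gene.seq = s_str
            return True
        start_bases = list(extras[0])
        s0 = start_bases[0]
        unprotected = [b for b in start_bases if b not in protected]
        if unprotected:
            b = unprotected[0]
            seq[b] = _pick_replacement(seq, b)
            continue
        # all three bases planted: allowed only inside exactly one ORF frame
        owners = [
            (s, e)
            for s, e in spans
            if any(s <= b < e for b in range(s0 - 2, s0 + 5))
        ]
        if len(set(owners)) != 1:
            return False
        os_, oe_ = owners[0]
        changed = False
        for b in start_bases:
            ci = (b - os_) // 3
            c_lo = os_ + 3 * ci
            codon = "".join(seq[c_lo : c_lo + 3])
            aa = oracle_translate_codon(codon)
            alts = [c for c in _SYNONYMS.get(aa, ()) if c != codon]
            if not alts:
                continue
            new = str(rng.choice(alts))
            seq[c_lo : c_lo + 3] = list(new)
            changed = True
            break
        if not changed:
            return False
    return False


def _make_coding_gene(gene: _Gene, spec: FixtureSpec, rng: np.random.Generator) -> bool:
    lo, hi = spec.utr_pad
    pad_a = _rand_background(rng, int(rng.integers(lo, hi)))
    u_codons = int(rng.integers(*spec.alt_orf_codons))
    uorf = _rand_orf(rng, u_codons)
    pad_b = _rand_background(rng, int(rng.integers(lo, hi)))
    utr5 = pad_a + uorf + pad_b

    n_cds = int(rng.integers(*spec.ref_orf_codons))
    cds = _rand_orf(rng, n_cds)

    # frame-overlapping ORF embedded at frame +1 inside the CDS
    ov_codons = int(rng.integers(*spec.overlap_orf_codons))
    ov_len = 3 * ov_codons
    ok = False
    for _ in range(200):
        c0 = int(rng.integers(4, n_cds - ov_codons - 6))
        p = 3 * c0 + 1
        ov = _rand_orf(rng, ov_codons)
        cand = cds[:p] + ov + cds[p + ov_len :]
        frame0 = [cand[i : i + 3] for i in range(0, len(cand) - 3, 3)]
        if all(c not in _STOPS for c in frame0):
            cds, ok = cand, True
            break
    if not ok:
        return False

    # in-frame 10-codon deletion for the isoform transcript, clear of the
    # overlap window and of the CDS termini
    del_codons = spec.isoform_deletion_codons
    ov_c_lo, ov_c_hi = (p - 1) // 3, (p + ov_len) // 3 + 2
    slots = [
        c
        for c in range(3, n_cds - del_codons - 3)
        if c + del_codons < ov_c_lo - 1 or c > ov_c_hi + 1
    ]
    if not slots:
        return False
    dc = int(rng.choice(slots))

    utr3 = _rand_background(rng, int(rng.integers(60, 140)))
    seq = utr5 + cds + utr3
    u5 = len(utr5)
    gene.seq = seq
    gene.cds_span = (u5, u5 + len(cds))
    gene.overlap_span = (u5 + p, u5 + p + ov_len)
    gene.deletion = (u5 + 3 * dc, u5 + 3 * dc + 3 * del_codons)
    gene.orfs = [
        _PlantedOrf("uORF", len(pad_a), len(pad_a) + len(uorf)),
        _PlantedOrf("refORF", u5, u5 + len(cds)),
        _PlantedOrf("overlapORF", u5 + p, u5 + p + ov_len),
    ]
    return _repair(gene, spec, rng)


def _make_noncoding_gene(gene: _Gene, spec: FixtureSpec, rng: np.random.Generator) -> bool:
    lo, hi = spec.utr_pad
    parts, orfs = [], []
    cursor = 0
    for i in range(2):
        pad = _rand_background(rng, int(rng.integers(lo, hi)))
        n = int(rng.integers(*spec.alt_orf_codons))
        orf = _rand_orf(rng, n)
        parts.extend([pad, orf])
        cursor += len(pad)
        orfs.append(_PlantedOrf(f"altORF{i + 1}", cursor, cursor + len(orf)))
        cursor += len(orf)
    parts.append(_rand_background(rng, int(rng.integers(lo, hi))))
    gene.seq = "".join(parts)
    gene.orfs = orfs
    return _repair(gene, spec, rng)


def _finalize_proteins(gene: _Gene) -> None:
    for o in gene.orfs:
        o.protein = _protein_of(gene.seq[o.t_start : o.t_end])


def _dissimilar_enough(gene: _Gene) -> bool:
    """Planted alternative proteins must stay clearly below the novel-isoform
    similarity thresholds against the gene's reference protein."""
    if gene.kind != "coding":
        return True
    ref_protein = next(o.protein for o in gene.orfs if o.label == "refORF")
    for o in gene.orfs:
        if o.label in ("uORF", "overlapORF"):
            _, identity, coverage = gotoh_local(o.protein, ref_protein)
            if identity >= 0.70 and coverage >= 0.40:
                return False
    return True


# ---------------------------------------------------------------------------
# genome placement


def _split_exons(
    gene: _Gene, spec: FixtureSpec, rng: np.random.Generator
) -> list[int]:
    """Transcript-space cut points (sorted) defining exon chunks of T1."""
    n_exons = int(rng.integers(spec.exons_per_transcript[0], spec.exons_per_transcript[1] + 1))
    if n_exons <= 1:
        return []
    forbidden = set()
    if gene.deletion:
        forbidden.update(range(gene.deletion[0] - 2, gene.deletion[1] + 2))
    candidates = [x for x in range(10, len(gene.seq) - 10) if x not in forbidden]
    cuts = sorted(int(c) for c in rng.choice(candidates, size=n_exons - 1, replace=False))
    # drop cuts closer than 10 nt to each other
    kept = []
    for c in cuts:
        if not kept or c - kept[-1] >= 10:
            kept.append(c)
    return kept


def _runs(gpos: list[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive genomic coordinates → exon intervals."""
    if not gpos:
        return []
    step = 1 if len(gpos) < 2 or gpos[1] > gpos[0] else -1
    runs = []
    run_start = gpos[0]
    prev = gpos[0]
    for g in gpos[1:]:
        if g != prev + step:
            runs.append((min(run_start, prev), max(run_start, prev) + 1))
            run_start = g
        prev = g
    runs.append((min(run_start, prev), max(run_start, prev) + 1))
    return runs


def _place_gene(
    gene: _Gene,
    chrom_seq: list[str],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> None:
    """Append the gene's genomic segment to ``chrom_seq`` and record the
    genomic position of every transcript base (5′→3′)."""
    cuts = _split_exons(gene, spec, rng)
    bounds = [0, *cuts, len(gene.seq)]
    chunks = [gene.seq[a:b] for a, b in zip(bounds, bounds[1:])]
    intron_lens = [
        int(rng.integers(*spec.intron_length)) for _ in range(len(chunks) - 1)
    ]
    offset = len(chrom_seq)
    if gene.strand == "+":
        t1_gpos: list[int] = []
        for i, chunk in enumerate(chunks):
            start = len(chrom_seq)
            chrom_seq.extend(chunk)
            t1_gpos.extend(range(start, start + len(chunk)))
            if i < len(intron_lens):
                chrom_seq.extend(_rand_background(rng, intron_lens[i]))
    else:
        # genomic layout left→right is the reverse complement of the
        # transcript: last chunk first, each reverse-complemented
        exon_intervals = []
        for i, chunk in enumerate(reversed(chunks)):
            start = len(chrom_seq)
            chrom_seq.extend(_rc(chunk))
            exon_intervals.append((start, start + len(chunk)))
            if i < len(intron_lens):
                chrom_seq.extend(_rand_background(rng, intron_lens[i]))
        exon_intervals.reverse()  # now in transcript order
        t1_gpos = []
        for g_lo, g_hi in exon_intervals:
            t1_gpos.extend(range(g_hi - 1, g_lo - 1, -1))
    gene.t1_gpos = t1_gpos
    if gene.deletion:
        d0, d1 = gene.deletion
        gene.t2_gpos = t1_gpos[:d0] + t1_gpos[d1:]
    assert len(t1_gpos) == len(gene.seq)
    del offset


# ---------------------------------------------------------------------------
# accession prediction (independent re-statement of the minting rule)


def _predict_accessions(
    protein_meta: dict[str, dict],
) -> dict[str, str]:
    """sequence → accession, numbering II_/IP_ in genomic order."""
    ordered = sorted(
        protein_meta.items(),
        key=lambda kv: (kv[1]["chrom"], kv[1]["first_block_start"], kv[0]),
    )
    acc: dict[str, str] = {}
    ii = ip = 0
    for seq, meta in ordered:
        if meta["class"] == "refprot":
            acc[seq] = meta["ref_accession"]
        elif meta["class"] == "novel_isoform":
            ii += 1
            acc[seq] = f"II_{ii}"
        else:
            ip += 1
            acc[seq] = f"IP_{ip}"
    return acc


# ---------------------------------------------------------------------------
# main generator


def generate_fixture(spec: FixtureSpec, out_dir: str) -> dict:
    """Write the full fixture file set into ``out_dir`` and return truth.

    The ground-truth dict is also written to ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)

    kinds = ["coding", "lncRNA", "pseudogene"]
    genes: list[_Gene] = []
    for gi in range(spec.n_genes):
        kind = kinds[gi % 3]
        for _attempt in range(40):
            gene = _Gene(index=gi, kind=kind)
            gene.gene_id = f"ENSG{gi:05d}"
            gene.gene_name = f"GENE{gi}"
            made = (
                _make_coding_gene(gene, spec, rng)
                if kind == "coding"
                else _make_noncoding_gene(gene, spec, rng)
            )
            if not made:
                continue
            _finalize_proteins(gene)
            if _dissimilar_enough(gene):
                genes.append(gene)
                break
        else:
            raise RuntimeError(f"could not generate gene {gi} after 40 attempts")

    # place genes on two chromosomes
    chrom_seqs: dict[str, list[str]] = {"chr1": [], "chr2": []}
    for gene in genes:
        gene.chrom = "chr1" if gene.index % 2 == 0 else "chr2"
        gene.strand = "+" if rng.random() < 0.5 else "-"
        chrom_seq = chrom_seqs[gene.chrom]
        chrom_seq.extend(_rand_background(rng, int(rng.integers(*spec.intergenic))))
        _place_gene(gene, chrom_seq, spec, rng)
    for chrom_seq in chrom_seqs.values():
        chrom_seq.extend(_rand_background(rng, 80))
    genome = {c: "".join(s) for c, s in chrom_seqs.items()}

    # transcript bookkeeping ------------------------------------------------
    biotype_of = {"coding": "protein_coding", "lncRNA": "lncRNA", "pseudogene": "pseudogene"}
    tx_meta: dict[str, dict] = {}
    truth_orfs: dict[str, list] = {}
    for gene in genes:
        t1 = f"ENST{gene.index:05d}T1"
        tx_meta[t1] = {
            "gene": gene, "gpos": gene.t1_gpos, "seq": gene.seq,
            "exons": _runs(gene.t1_gpos),
            "biotype": biotype_of[gene.kind],
        }
        truth_orfs[t1] = [
            [o.t_start, o.t_end, o.protein, o.label] for o in gene.orfs
        ]
        if gene.deletion:
            d0, d1 = gene.deletion
            t2 = f"ENST{gene.index:05d}T2"
            t2_seq = gene.seq[:d0] + gene.seq[d1:]
            tx_meta[t2] = {
                "gene": gene, "gpos": gene.t2_gpos, "seq": t2_seq,
                "exons": _runs(gene.t2_gpos),
                "biotype": biotype_of[gene.kind],
            }
            shift = d1 - d0
            t2_orfs = []
            for o in gene.orfs:
                s2 = o.t_start if o.t_start < d0 else o.t_start - shift
                e2 = o.t_end - shift if o.label == "refORF" else (
                    o.t_end if o.t_end <= d0 else o.t_end - shift
                )
                label = "isoformORF" if o.label == "refORF" else o.label
                t2_orfs.append([s2, e2, _protein_of(t2_seq[s2:e2]), label])
            truth_orfs[t2] = t2_orfs

    # protein-level truth ---------------------------------------------------
    protein_meta: dict[str, dict] = {}
    for tx_id, meta in tx_meta.items():
        gene = meta["gene"]
        for t_start, t_end, protein, label in truth_orfs[tx_id]:
            block_start = min(meta["gpos"][t_start], meta["gpos"][t_end - 1])
            cls = {
                "refORF": "refprot",
                "isoformORF": "novel_isoform",
            }.get(label, "altprot")
            rec = protein_meta.setdefault(
                protein,
                {
                    "class": cls,
                    "genes": set(),
                    "transcripts": set(),
                    "chrom": gene.chrom,
                    "first_block_start": block_start,
                    "ref_accession": f"REF{gene.index:05d}" if cls == "refprot" else "",
                    "labels": set(),
                },
            )
            rec["genes"].add(gene.gene_id)
            rec["transcripts"].add(tx_id)
            rec["first_block_start"] = min(rec["first_block_start"], block_start)
            rec["labels"].add(label)
    accession_of = _predict_accessions(protein_meta)

    # ----------------------------------------------------------------- files
    paths = {name: os.path.join(out_dir, name) for name in (
        "genome.fa", "annotation.gff3", "annotation.gtf", "ref_proteome.fa",
        "psms.tsv", "ribo.tsv", "disorder.tsv", "slims.tsv", "structure.tsv",
        "expression.tsv", "variants.vcf", "truth.json",
    )}

    with open(paths["genome.fa"], "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    _write_annotations(paths, tx_meta)

    with open(paths["ref_proteome.fa"], "w") as fh:
        for gene in genes:
            if gene.kind != "coding":
                continue
            protein = next(o.protein for o in gene.orfs if o.label == "refORF")
            fh.write(f">REF{gene.index:05d} GN={gene.gene_id}\n{protein}\n")
        # UniProt-like entries encoded nowhere in the mini-genome
        for j in range(3):
            decoy_prot = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=int(rng.integers(40, 80)))
            )
            fh.write(f">UPX{j:03d} GN=GENE_UNLINKED{j}\n{decoy_prot}\n")

    truth = _plant_evidence_and_annotations(spec, rng, paths, protein_meta, accession_of, tx_meta)

    truth.update(
        {
            "transcripts": {
                tx: {
                    "gene_id": m["gene"].gene_id,
                    "biotype": m["biotype"],
                    "strand": m["gene"].strand,
                    "chrom": m["gene"].chrom,
                    "exons": m["exons"],
                    "spliced_length": len(m["seq"]),
                }
                for tx, m in tx_meta.items()
            },
            "orfs": truth_orfs,
            "proteins": {
                accession_of[seq]: {
                    "sequence": seq,
                    "class": meta["class"],
                    "genes": sorted(meta["genes"]),
                    "transcripts": sorted(meta["transcripts"]),
                }
                for seq, meta in protein_meta.items()
            },
        }
    )

    truth["variants"] = _plant_variants(spec, rng, paths, genome, tx_meta, truth_orfs, accession_of)

    with open(paths["truth.json"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=list)
    return truth


def _write_annotations(paths: dict, tx_meta: dict) -> None:
    gff = open(paths["annotation.gff3"], "w")
    gtf = open(paths["annotation.gtf"], "w")
    gff.write("##gff-version 3\n")
    seen_genes = set()
    for tx_id in sorted(tx_meta):
        m = tx_meta[tx_id]
        gene = m["gene"]
        chrom, strand, biotype = gene.chrom, gene.strand, m["biotype"]
        exons = sorted(m["exons"])
        lo, hi = exons[0][0], exons[-1][1]
        if gene.gene_id not in seen_genes:
            seen_genes.add(gene.gene_id)
            gff.write(
                f"{chrom}\tsynthetic\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id};gene_id={gene.gene_id};gene_name={gene.gene_name}\n"
            )
            gtf.write(
                f'{chrom}\tsynthetic\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t'
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}";\n'
            )
        gff.write(
            f"{chrom}\tsynthetic\ttranscript\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
            f"ID={tx_id};Parent={gene.gene_id};gene_id={gene.gene_id};"
            f"gene_name={gene.gene_name};biotype={biotype}\n"
        )
        gtf.write(
            f'{chrom}\tsynthetic\ttranscript\t{lo + 1}\t{hi}\t.\t{strand}\t.\t'
            f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}"; '
            f'gene_name "{gene.gene_name}"; transcript_biotype "{biotype}";\n'
        )
        for s, e in exons:
            gff.write(
                f"{chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={tx_id}\n"
            )
            gtf.write(
                f'{chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t'
                f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";\n'
            )
    gff.close()
    gtf.close()


def _unique_peptide(
    rng: np.random.Generator,
    protein: str,
    all_sequences: list[str],
    used: set[str],
) -> str | None:
    """A 9–12-mer substring occurring (I/L-collapsed) in exactly one sequence."""
    collapse = lambda s: s.replace("L", "I")
    for _ in range(60):
        k = int(rng.integers(9, 13))
        if len(protein) < k:
            return None
        i = int(rng.integers(0, len(protein) - k + 1))
        pep = protein[i : i + k]
        if pep in used:
            continue
        hits = sum(1 for s in all_sequences if collapse(pep) in collapse(s))
        if hits == 1:
            used.add(pep)
            return pep
    return None


def _plant_evidence_and_annotations(
    spec, rng, paths, protein_meta, accession_of, tx_meta
) -> dict:
    sequences = list(protein_meta)
    truth_ev: dict[str, dict] = {}
    psm_rows: list[tuple[str, float, int, str]] = []
    ribo_rows: list[tuple[str, int]] = []
    used_peptides: set[str] = set()

    # deterministic per-protein plan, cycling detection scenarios
    plan_cycle = [(2, 0), (1, 1), (1, 0), (0, 2), (2, 1)]
    ordered_acc = sorted(accession_of[s] for s in sequences)
    seq_by_acc = {accession_of[s]: s for s in sequences}
    for i, acc in enumerate(ordered_acc):
        n_pep, n_ribo = plan_cycle[i % len(plan_cycle)]
        protein = seq_by_acc[acc]
        got = 0
        for _ in range(n_pep):
            pep = _unique_peptide(rng, protein, sequences, used_peptides)
            if pep is None:
                break
            psm_rows.append((pep, float(np.round(rng.uniform(8, 12), 3)), 0, "DS1"))
            got += 1
        if n_ribo:
            ribo_rows.append((acc, n_ribo))
        detected = got >= 2 or (got >= 1 and n_ribo >= 1)
        truth_ev[acc] = {
            "unique_peptides": got,
            "riboseq_detections": n_ribo,
            "detected": detected,
        }
    # decoys: reversed peptides, scores strictly below every target
    for pep, _, _, _ in list(psm_rows)[:: 4]:
        psm_rows.append((pep[::-1], float(np.round(rng.uniform(0, 4), 3)), 1, "DS1"))

    with open(paths["psms.tsv"], "w") as fh:
        fh.write("peptide\tscore\tis_decoy\tdataset\n")
        for pep, score, decoy, ds in psm_rows:
            fh.write(f"{pep}\t{score}\t{decoy}\t{ds}\n")
    with open(paths["ribo.tsv"], "w") as fh:
        fh.write("accession\tdetections\n")
        for acc, n in ribo_rows:
            fh.write(f"{acc}\t{n}\n")

    # multi-coding truth
    multicoding = {}
    for tx_id in tx_meta:
        accs = [
            accession_of[s]
            for s, m in protein_meta.items()
            if tx_id in m["transcripts"]
        ]
        detected = sorted(a for a in accs if truth_ev[a]["detected"])
        multicoding[tx_id] = {"detected_proteins": detected, "is_multicoding": len(detected) >= 2}

    # disorder profiles & IDR truth (planted run lengths cycle 29 / 28 / none)
    truth_idr: dict[str, list] = {}
    disorder_rows = []
    for i, acc in enumerate(ordered_acc):
        n = len(seq_by_acc[acc])
        flags = ["0"] * n
        mode = i % 4
        if mode == 0 and n >= spec.idr_min_run:
            start = int(rng.integers(0, n - spec.idr_min_run + 1))
            run = spec.idr_min_run
        elif mode == 1 and n >= spec.idr_min_run - 1:
            start = int(rng.integers(0, n - (spec.idr_min_run - 1) + 1))
            run = spec.idr_min_run - 1
        else:
            start, run = 0, 0
        for j in range(start, start + run):
            flags[j] = "1"
        disorder_rows.append((acc, "".join(flags)))
        truth_idr[acc] = [[start, start + run]] if run >= spec.idr_min_run else []
    with open(paths["disorder.tsv"], "w") as fh:
        fh.write("accession\tflags\n")
        for acc, flags in disorder_rows:
            fh.write(f"{acc}\t{flags}\n")

    # SLiMs: one fully inside each planted IDR (retained), one straddling
    # its edge (filtered out); coordinates 1-based inclusive on disk
    slim_rows, truth_slims = [], {}
    for acc, regions in truth_idr.items():
        retained = []
        if regions:
            s, e = regions[0]
            inside = (s + 3, min(s + 10, e))
            slim_rows.append((acc, f"MOT_IN_{acc}", inside[0] + 1, inside[1]))
            retained.append(f"MOT_IN_{acc}")
            n = len(seq_by_acc[acc])
            if e < n:
                slim_rows.append((acc, f"MOT_OUT_{acc}", e - 2, min(e + 3, n)))
            elif s > 1:
                slim_rows.append((acc, f"MOT_OUT_{acc}", s - 1, s + 4))
        truth_slims[acc] = retained
    with open(paths["slims.tsv"], "w") as fh:
        fh.write("accession\tmotif_id\tstart\tend\n")
        for acc, motif, s1, e1 in slim_rows:
            fh.write(f"{acc}\t{motif}\t{s1}\t{e1}\n")

    # structure confidence: pLDDT spread over the bins, MSA depth straddling
    # the routing boundary
    truth_bins, truth_pred = {}, {}
    with open(paths["structure.tsv"], "w") as fh:
        fh.write("accession\tplddt\tmsa_depth\n")
        for i, acc in enumerate(ordered_acc):
            plddt = float(np.round(rng.uniform(20, 100), 1))
            depth = int(rng.integers(2, 200))
            if i % 7 == 0:
                depth = 29
            elif i % 7 == 1:
                depth = 30
            fh.write(f"{acc}\t{plddt}\t{depth}\n")
            if plddt > 90:
                b = "very_high"
            elif plddt > 70:
                b = "high"
            elif plddt > 50:
                b = "medium"
            else:
                b = "very_low"
            truth_bins[acc] = b
            truth_pred[acc] = "omegafold-like" if depth < 30 else "alphafold-like"

    # transcript expression
    tpms = {
        tx: float(np.round(np.exp(rng.normal(1.5, spec.tpm_sigma)), 3))
        for tx in sorted(tx_meta)
    }
    with open(paths["expression.tsv"], "w") as fh:
        fh.write("transcript_id\ttpm\n")
        for tx, tpm in sorted(tpms.items()):
            fh.write(f"{tx}\t{tpm}\n")
    expression_rank = [t for t, _ in sorted(tpms.items(), key=lambda kv: (-kv[1], kv[0]))]

    return {
        "evidence": truth_ev,
        "multicoding": multicoding,
        "idrs": truth_idr,
        "slims_retained": truth_slims,
        "plddt_bins": truth_bins,
        "predictors": truth_pred,
        "expression": tpms,
        "expression_rank": expression_rank,
    }


def _variant_calls_truth(
    chrom: str, pos: int, ref: str, alt: str, tx_meta, truth_orfs, accession_of
) -> dict:
    """Expected per-ORF consequences for one variant (oracle-derived)."""
    calls: dict[str, dict] = {}
    for tx_id, m in tx_meta.items():
        gene = m["gene"]
        if gene.chrom != chrom:
            continue
        g_lo, g_hi = min(m["gpos"]), max(m["gpos"]) + 1
        if pos + len(ref) <= g_lo or pos >= g_hi:
            continue
        edit = oracle_project_edit(m["gpos"], gene.strand, pos, ref, alt)
        per_orf = {}
        for t_start, t_end, protein, _label in truth_orfs[tx_id]:
            cons = oracle_variant_consequence(m["seq"], t_start, t_end, edit)
            per_orf[f"{tx_id}:{t_start}-{t_end}"] = cons
        calls[tx_id] = per_orf
    return calls


def _plant_variants(
    spec, rng, paths, genome, tx_meta, truth_orfs, accession_of
) -> dict:
    variants: list[tuple[str, int, str, str, str]] = []  # id, pos(0b), ref, alt, chrom
    truth: dict[str, dict] = {}
    vid = 0

    def add(chrom: str, pos: int, ref: str, alt: str) -> None:
        nonlocal vid
        vid += 1
        name = f"var{vid}"
        variants.append((name, pos, ref, alt, chrom))
        truth[name] = {
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "calls": _variant_calls_truth(chrom, pos, ref, alt, tx_meta, truth_orfs, accession_of),
        }

    coding = [
        (tx_id, m)
        for tx_id, m in sorted(tx_meta.items())
        if m["gene"].kind == "coding" and m["gene"].seq == m["seq"]
    ]
    for tx1, m in coding[: max(6, len(coding) // 2)]:
        gene = m["gene"]
        gpos, seq = m["gpos"], m["seq"]
        cds_lo, cds_hi = gene.cds_span
        ov_lo, ov_hi = gene.overlap_span
        d0, d1 = gene.deletion

        def g_ref(t_pos: int) -> tuple[int, str]:
            g = gpos[t_pos]
            base = genome[gene.chrom][g]
            return g, base

        # 1) synonymous SNV at a wobble position of the reference ORF
        planted = False
        interior = [
            c for c in range(2, (cds_hi - cds_lo) // 3 - 2)
            if not (ov_lo <= cds_lo + 3 * c + 2 < ov_hi + 3)
            and not (d0 - 3 <= cds_lo + 3 * c < d1 + 3)
        ]
        rng.shuffle(interior)
        for c in interior[:25]:
            t_pos = cds_lo + 3 * c + 2
            g, base = g_ref(t_pos)
            for alt_base in "ACGT":
                if alt_base == base:
                    continue
                calls = _variant_calls_truth(gene.chrom, g, base, alt_base, tx_meta, truth_orfs, accession_of)
                key = f"{tx1}:{cds_lo}-{cds_hi}"
                if calls.get(tx1, {}).get(key) == "synonymous":
                    add(gene.chrom, g, base, alt_base)
                    planted = True
                    break
            if planted:
                break

        # 2) SNV inside the frame-overlap region with divergent consequences
        planted = False
        ov_positions = list(range(ov_lo + 4, ov_hi - 4))
        rng.shuffle(ov_positions)
        for t_pos in ov_positions[:40]:
            g, base = g_ref(t_pos)
            for alt_base in "ACGT":
                if alt_base == base:
                    continue
                calls = _variant_calls_truth(gene.chrom, g, base, alt_base, tx_meta, truth_orfs, accession_of)
                c_ref = calls.get(tx1, {}).get(f"{tx1}:{cds_lo}-{cds_hi}")
                c_ov = calls.get(tx1, {}).get(f"{tx1}:{ov_lo}-{ov_hi}")
                if c_ref and c_ov and c_ref != c_ov and "non_orf" not in (c_ref, c_ov):
                    add(gene.chrom, g, base, alt_base)
                    planted = True
                    break
            if planted:
                break

        # 3) 1-nt insertion inside the CDS (frameshift), anchored so that
        # left-normalisation cannot move it
        ins_slots = [
            t for t in range(cds_lo + 9, cds_hi - 9)
            if not (ov_lo - 3 <= t < ov_hi + 3) and not (d0 - 3 <= t < d1 + 3)
        ]
        rng.shuffle(ins_slots)
        for t_pos in ins_slots[:20]:
            g, base = g_ref(t_pos)
            choices = [b for b in "ACGT" if b != base]
            ins = str(rng.choice(choices))
            add(gene.chrom, g, base, base + ins)
            break

        # 4) stop-lost SNV: first base of the reference stop codon → C
        t_pos = cds_hi - 3
        g, base = g_ref(t_pos)
        alt_base = "C" if base != "C" else "G"
        add(gene.chrom, g, base, alt_base)

        # 5) 3′UTR SNV (within the transcript, outside every ORF)
        t_pos = cds_hi + 5
        if t_pos < len(seq):
            g, base = g_ref(t_pos)
            alt_base = "T" if base != "T" else "A"
            add(gene.chrom, g, base, alt_base)

    # multi-allelic intergenic site on chr1 (splits into two records)
    base = genome["chr1"][5]
    alts = [b for b in "ACGT" if b != base][:2]
    vid += 1
    variants.append((f"var{vid}", 5, base, ",".join(alts), "chr1"))
    truth[f"var{vid}"] = {"chrom": "chr1", "pos": 5, "ref": base, "alt": ",".join(alts), "calls": {}}

    with open(paths["variants.vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in genome.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for name, pos, ref, alt, chrom in sorted(variants, key=lambda v: (v[4], v[1])):
            fh.write(f"{chrom}\t{pos + 1}\t{name}\t{ref}\t{alt}\t.\tPASS\t.\n")
    return truth
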