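"""End-to-end pipeline: annotate → classify → evidence → postprocess →
variants → custom database, with provenance metadata on every output."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .classify import (
    DEFAULT_COV_THRESHOLD,
    DEFAULT_ID_THRESHOLD,
    ClassifiedProtein,
    ReferenceProteome,
    classify,
    mint_accessions,
)
from .customdb import CustomDbConfig, build_custom_db
from .evidence import DEFAULT_FDR_MAX, evidence_call, fdr_filter, flag_multicoding, map_peptides
from .genome_io import merge_annotations, read_annotation, read_genome, spliced_sequence
from .orfs import DEFAULT_MIN_CODONS, DEFAULT_START_CODONS, deduplicate, enumerate_orfs
from .postprocess import DEFAULT_DISORDER_THRESHOLD, DEFAULT_MIN_RUN, call_idrs, filter_slims, idr_prevalence
from .tables import (
    read_disorder_tsv,
    read_expression_tsv,
    read_psm_tsv,
    read_ribo_tsv,
    read_slim_tsv,
    read_structure_tsv,
)
from .variants import annotate_variant, mutated_protein_sequence, read_vcf, summarize_impacts
from .writers import write_annotation_tsv, write_orf_bed, write_protein_fasta


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds; recorded verbatim in outputs."""

    genome: str = ""
    gff: str = ""
    gff2: str = ""  # optional second annotation source (merged by gene)
    ref_proteome: str = ""
    psm: str = ""
    ribo: str = ""
    disorder: str = ""
    slims: str = ""
    structure: str = ""
    expression: str = ""
    vcf: str = ""
    out_dir: str = "altorf_out"
    min_codons: int = DEFAULT_MIN_CODONS
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    all_starts: bool = False
    id_threshold: float = DEFAULT_ID_THRESHOLD
    cov_threshold: float = DEFAULT_COV_THRESHOLD
    fdr_max: float = DEFAULT_FDR_MAX
    il_equivalent: bool = True
    disorder_threshold: float = DEFAULT_DISORDER_THRESHOLD
    idr_min_run: int = DEFAULT_MIN_RUN
    max_proteins: int = 100_000
    min_tpm: float = 0.0
    seed: int = 0
    threads: int = 1  # accepted and recorded; results are thread-count independent

    _PATH_FIELDS = frozenset({
        "genome", "gff", "gff2", "ref_proteome", "psm", "ribo", "disorder",
        "slims", "structure", "expression", "vcf", "out_dir",
    })

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so identical
        analyses of the same data hash identically wherever they run)."""
        payload = json.dumps(
            {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def metadata(self) -> list[str]:
        return [f"altorf_version={__version__}", f"config_hash={self.config_hash()}"]


@dataclass
class PipelineResult:
    transcripts: dict = field(default_factory=dict)
    spliced: dict = field(default_factory=dict)
    orfs_by_transcript: dict = field(default_factory=dict)
    proteins: list[ClassifiedProtein] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)
    multicoding: dict = field(default_factory=dict)
    idr_calls: dict = field(default_factory=dict)
    idr_prevalence: dict = field(default_factory=dict)
    slims_retained: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)
    consequence_calls: list = field(default_factory=list)
    custom_db: object = None


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run all configured stages; writes outputs under ``cfg.out_dir``."""
    required = [cfg.genome, cfg.gff, cfg.ref_proteome]
    optional = [cfg.gff2, cfg.psm, cfg.ribo, cfg.disorder, cfg.slims,
                cfg.structure, cfg.expression, cfg.vcf]
    for path in required + [p for p in optional if p]:
        if not os.path.exists(path):
            raise FileNotFoundError(f"input file missing: {path}")
    os.makedirs(cfg.out_dir, exist_ok=True)
    meta = cfg.metadata()
    res = PipelineResult()

    # --- annotate ---------------------------------------------------------
    genome = read_genome(cfg.genome)
    transcripts = read_annotation(cfg.gff, "ensembl-like")
    if cfg.gff2:
        transcripts = merge_annotations(transcripts, read_annotation(cfg.gff2, "refseq-like"))
    res.transcripts = {t.transcript_id: t for t in transcripts}
    all_orfs = []
    for t in transcripts:
        seq = spliced_sequence(t, genome)
        res.spliced[t.transcript_id] = seq
        orfs = enumerate_orfs(t, seq, cfg.min_codons, cfg.start_codons, cfg.all_starts)
        res.orfs_by_transcript[t.transcript_id] = orfs
        all_orfs.extend(orfs)
    records = deduplicate(all_orfs, res.transcripts)

    # --- classify ---------------------------------------------------------
    ref = ReferenceProteome.from_fastas(cfg.ref_proteome)
    classified = [classify(r, ref, cfg.id_threshold, cfg.cov_threshold) for r in records]
    res.proteins = mint_accessions(classified)
    write_protein_fasta(res.proteins, os.path.join(cfg.out_dir, "proteins.fa"), meta)
    write_orf_bed(all_orfs, os.path.join(cfg.out_dir, "orfs.bed"), meta)

    # --- evidence ---------------------------------------------------------
    if cfg.psm:
        accepted = fdr_filter(read_psm_tsv(cfg.psm), cfg.fdr_max)
        peptides = sorted({p.peptide for p in accepted})
        counts = map_peptides(peptides, res.proteins, ref, cfg.il_equivalent)
        ribo = read_ribo_tsv(cfg.ribo) if cfg.ribo else {}
        res.evidence = {
            cp.accession: evidence_call(
                cp.accession, counts.get(cp.accession, 0), ribo.get(cp.accession, 0)
            )
            for cp in res.proteins
        }
        tx_proteins = {
            tx_id: [o.accession for o in orfs]
            for tx_id, orfs in res.orfs_by_transcript.items()
        }
        res.multicoding = flag_multicoding(tx_proteins, res.evidence)

    gene_names = {t.gene_id: t.gene_name for t in transcripts}
    write_annotation_tsv(
        res.proteins, os.path.join(cfg.out_dir, "annotation.tsv"),
        res.evidence or None, gene_names, meta,
    )

    # --- postprocess ------------------------------------------------------
    lengths = {cp.accession: len(cp.sequence) for cp in res.proteins}
    if cfg.disorder:
        profiles = read_disorder_tsv(cfg.disorder)
        for acc, profile in profiles.items():
            res.idr_calls[acc] = call_idrs(
                profile, cfg.disorder_threshold, cfg.idr_min_run, lengths.get(acc)
            )
        classes = {cp.accession: cp.cls for cp in res.proteins}
        res.idr_prevalence = idr_prevalence(classes, res.idr_calls)
        if cfg.slims:
            for acc, slims in read_slim_tsv(cfg.slims).items():
                if acc in profiles:
                    res.slims_retained[acc] = filter_slims(
                        slims, profiles[acc], cfg.disorder_threshold
                    )
    if cfg.structure:
        res.structure = read_structure_tsv(cfg.structure)

    # --- variants ---------------------------------------------------------
    variant_proteins: dict[tuple[str, str], str] = {}
    if cfg.vcf:
        for v in read_vcf(cfg.vcf, genome):
            calls = annotate_variant(
                v, res.orfs_by_transcript, res.transcripts, res.spliced, cfg.start_codons
            )
            res.consequence_calls.extend(calls)
            for call in calls:
                if call.impact in ("moderate", "high"):
                    orf = next(
                        o for o in res.orfs_by_transcript[call.transcript_id]
                        if o.orf_id == call.orf_id
                    )
                    mut = mutated_protein_sequence(
                        v, orf, res.transcripts[call.transcript_id],
                        res.spliced[call.transcript_id], cfg.start_codons,
                    )
                    if mut:
                        variant_proteins[(call.variant_key, call.orf_id)] = mut
        _write_consequences(
            res.consequence_calls, os.path.join(cfg.out_dir, "consequences.tsv"),
            {cp.accession: cp.cls for cp in res.proteins}, meta,
        )

    # --- custom database --------------------------------------------------
    if cfg.expression:
        expr = read_expression_tsv(cfg.expression)
        db_cfg = CustomDbConfig(max_proteins=cfg.max_proteins, min_tpm=cfg.min_tpm)
        res.custom_db = build_custom_db(
            expr, res.proteins, db_cfg, res.consequence_calls or None, variant_proteins
        )
        res.custom_db.write_fasta(os.path.join(cfg.out_dir, "custom_db.fa"))
        res.custom_db.write_manifest(os.path.join(cfg.out_dir, "custom_db_manifest.tsv"))
    return res


def _write_consequences(calls, path: str, classes: dict[str, str], meta: list[str]) -> None:
    with open(path, "w") as fh:
        for line in meta:
            fh.write(f"#{line}\n")
        fh.write("variant\ttranscript\torf\taccession\tclass\tconsequence\timpact\tnote\n")
        for c in calls:
            fh.write(
                f"{c.variant_key}\t{c.transcript_id}\t{c.orf_id}\t{c.accession}\t"
                f"{classes.get(c.accession, 'unclassified')}\t{c.consequence}\t{c.impact}\t{c.note}\n"
            )
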