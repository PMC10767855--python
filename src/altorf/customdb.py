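"""Expression-ranked custom protein database construction.

Transcripts are ranked by expression (TPM, ties broken lexicographically by
transcript id) and admitted whole — all the proteins a transcript encodes,
plus variant isoforms of its ORFs — until admitting the next transcript
would exceed the protein cap (100 000 by default). An inclusion or
exclusion list overrides the expression ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ClassifiedProtein
from .variants import ConsequenceCall

DEFAULT_MAX_PROTEINS = 100_000

_VARIANT_EMITTING = {"missense", "inframe_insertion", "inframe_deletion",
                     "stop_gained", "stop_lost", "frameshift"}


@dataclass
class CustomDbConfig:
    max_proteins: int = DEFAULT_MAX_PROTEINS
    include_list: set[str] | None = None
    exclude_list: set[str] | None = None
    min_tpm: float = 0.0
    emit_reference_with_variant: bool = True

    def __post_init__(self) -> None:
        if self.max_proteins < 1:
            raise ValueError("max_proteins must be ≥1")
        if self.include_list and self.exclude_list:
            overlap = self.include_list & self.exclude_list
            if overlap:
                raise ValueError(f"transcripts on both include and exclude lists: {sorted(overlap)}")


@dataclass
class DbEntry:
    accession: str
    sequence: str
    transcript_id: str
    tpm: float
    variant_tag: str = ""


@dataclass
class CustomDb:
    entries: list[DbEntry] = field(default_factory=list)
    admitted_transcripts: list[str] = field(default_factory=list)

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                tag = f" VAR={e.variant_tag}" if e.variant_tag else ""
                fh.write(f">{e.accession} TX={e.transcript_id} TPM={e.tpm:g}{tag}\n")
                for i in range(0, len(e.sequence), 60):
                    fh.write(e.sequence[i : i + 60] + "\n")

    def write_manifest(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("accession\ttranscript_id\ttpm\tvariant\tlength\n")
            for e in self.entries:
                fh.write(
                    f"{e.accession}\t{e.transcript_id}\t{e.tpm:g}\t{e.variant_tag or '-'}\t{len(e.sequence)}\n"
                )


def _rank_transcripts(
    expr: dict[str, float], cfg: CustomDbConfig
) -> list[tuple[str, float]]:
    items = expr.items()
    if cfg.include_list is not None:
        items = [(t, x) for t, x in items if t in cfg.include_list]
    if cfg.exclude_list:
        items = [(t, x) for t, x in items if t not in cfg.exclude_list]
    items = [(t, x) for t, x in items if x >= cfg.min_tpm]
    return sorted(items, key=lambda kv: (-kv[1], kv[0]))


def build_custom_db(
    expr: dict[str, float],
    proteins: list[ClassifiedProtein],
    cfg: CustomDbConfig,
    variant_calls: list[ConsequenceCall] | None = None,
    variant_proteins: dict[tuple[str, str], str] | None = None,
) -> CustomDb:
    """Greedy transcript-rank fill of a sample-specific protein database.

    ``variant_proteins`` maps (variant_key, orf_id) → full mutated protein
    sequence for coding variants; when provided, the variant sequence is
    emitted alongside the reference sequence with a suffixed accession.
    """
    by_transcript: dict[str, list[ClassifiedProtein]] = {}
    for cp in proteins:
        for tx in sorted(cp.record.transcripts):
            by_transcript.setdefault(tx, []).append(cp)

    coding_calls: dict[str, list[ConsequenceCall]] = {}
    for call in variant_calls or []:
        if call.consequence in _VARIANT_EMITTING:
            coding_calls.setdefault(call.transcript_id, []).append(call)

    db = CustomDb()
    admitted_acc: set[str] = set()
    emitted_variant: set[tuple[str, str]] = set()
    for tx_id, tpm in _rank_transcripts(expr, cfg):
        cps = by_transcript.get(tx_id, [])
        batch: list[DbEntry] = []
        for cp in sorted(cps, key=lambda c: c.accession):
            if cp.accession not in admitted_acc:
                batch.append(DbEntry(cp.accession, cp.sequence, tx_id, tpm))
            for call in coding_calls.get(tx_id, []):
                if call.accession != cp.accession:
                    continue
                key = (call.variant_key, call.orf_id)
                if key in emitted_variant:
                    continue
                if not variant_proteins or key not in variant_proteins:
                    continue  # full mutated sequence unavailable
                var_seq = variant_proteins[key]
                batch.append(
                    DbEntry(
                        f"{cp.accession}@{call.variant_key}",
                        var_seq,
                        tx_id,
                        tpm,
                        variant_tag=call.variant_key,
                    )
                )
                emitted_variant.add(key)
        if len(db.entries) + len(batch) > cfg.max_proteins:
            break
        db.entries.extend(batch)
        admitted_acc.update(e.accession for e in batch if not e.variant_tag)
        db.admitted_transcripts.append(tx_id)
    return db
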