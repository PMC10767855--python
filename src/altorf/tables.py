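"""Tabular (TSV) input readers for evidence and annotation side-channels.

All readers go through pandas; 1-based inclusive coordinates in SLiM tables
are converted to the internal 0-based half-open convention here.
"""

from __future__ import annotations

import pandas as pd

from .evidence import PsmRecord
from .postprocess import DisorderProfile, SlimMatch, StructureConfidence


def read_psm_tsv(path: str) -> list[PsmRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PsmRecord(
            peptide=str(r.peptide),
            score=float(r.score),
            is_decoy=bool(int(r.is_decoy)),
            dataset_id=str(getattr(r, "dataset", "")),
        )
        for r in df.itertuples(index=False)
    ]


def read_ribo_tsv(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["accession"].astype(str), df["detections"].astype(int)))


def read_disorder_tsv(path: str) -> dict[str, DisorderProfile]:
    """Flag strings ("0101...") or comma-separated propensities per protein."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    profiles = {}
    for r in df.itertuples(index=False):
        acc = str(r.accession)
        raw = str(r.flags)
        if set(raw) <= {"0", "1"}:
            profiles[acc] = DisorderProfile(acc, flags=[c == "1" for c in raw])
        else:
            profiles[acc] = DisorderProfile(
                acc, propensities=[float(x) for x in raw.split(",")]
            )
    return profiles


def read_slim_tsv(path: str) -> dict[str, list[SlimMatch]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    slims: dict[str, list[SlimMatch]] = {}
    for r in df.itertuples(index=False):
        acc = str(r.accession)
        # 1-based inclusive on disk → 0-based half-open
        slims.setdefault(acc, []).append(
            SlimMatch(acc, str(r.motif_id), int(r.start) - 1, int(r.end))
        )
    return slims


def read_structure_tsv(path: str) -> dict[str, StructureConfidence]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r.accession): StructureConfidence(
            str(r.accession), float(r.plddt), int(r.msa_depth)
        )
        for r in df.itertuples(index=False)
    }


def read_expression_tsv(path: str) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    tpm = df["tpm"].astype(float)
    if (tpm < 0).any():
        raise ValueError("negative TPM values in expression table")
    return dict(zip(df["transcript_id"].astype(str), tpm))
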