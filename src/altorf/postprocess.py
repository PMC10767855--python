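"""Post-prediction functional filters over externally produced scores.

This module never runs a disorder or structure predictor; it consumes their
per-residue/per-protein outputs (tabular) and applies the resource's rules:

* IDR calling — maximal runs of ≥29 consecutive disordered residues (the
  shortest predicted proteins are 29 aa, hence the 29 rather than the more
  common 30-residue convention).
* SLiM filtering — a short linear motif is kept only when every residue in
  its span is predicted disordered.
* pLDDT confidence binning — very_high (>90), high (70,90], medium (50,70],
  very_low (≤50); boundary values fall in the lower bin.
* Structure-predictor routing — alignment-free prediction when the multiple
  sequence alignment holds fewer than 30 sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_MIN_RUN = 29
DEFAULT_DISORDER_THRESHOLD = 0.5
MSA_DEPTH_CUTOFF = 30

VERY_HIGH = "very_high"
HIGH = "high"
MEDIUM = "medium"
VERY_LOW = "very_low"

ALPHAFOLD_LIKE = "alphafold-like"
OMEGAFOLD_LIKE = "omegafold-like"


@dataclass
class DisorderProfile:
    """Per-residue disorder flags or propensities for one protein."""

    accession: str
    flags: list[bool] | None = None
    propensities: list[float] | None = None

    def __post_init__(self) -> None:
        if (self.flags is None) == (self.propensities is None):
            raise ValueError("provide exactly one of flags or propensities")

    def __len__(self) -> int:
        return len(self.flags if self.flags is not None else self.propensities)

    def binary(self, threshold: float = DEFAULT_DISORDER_THRESHOLD) -> list[bool]:
        if self.flags is not None:
            return list(self.flags)
        return [p >= threshold for p in self.propensities]


@dataclass(frozen=True)
class IdrRegion:
    accession: str
    start: int  # 0-based half-open residue indices
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SlimMatch:
    accession: str
    motif_id: str
    start: int  # 0-based half-open residue indices
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty SLiM span")


def call_idrs(
    profile: DisorderProfile,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    protein_length: int | None = None,
) -> list[IdrRegion]:
    """Maximal runs of ≥ ``min_run`` consecutive disordered residues."""
    if len(profile) == 0:
        raise ValueError("empty disorder profile")
    if protein_length is not None and protein_length != len(profile):
        raise ValueError(
            f"{profile.accession}: profile length {len(profile)} != protein length {protein_length}"
        )
    flags = profile.binary(threshold)
    regions = []
    run_start = None
    for i, disordered in enumerate(flags + [False]):
        if disordered and run_start is None:
            run_start = i
        elif not disordered and run_start is not None:
            if i - run_start >= min_run:
                regions.append(IdrRegion(profile.accession, run_start, i))
            run_start = None
    return regions


def filter_slims(
    slims: list[SlimMatch],
    profile: DisorderProfile,
    threshold: float = DEFAULT_DISORDER_THRESHOLD,
) -> list[SlimMatch]:
    """Retain only SLiMs whose every residue is predicted disordered."""
    flags = profile.binary(threshold)
    retained = []
    for slim in slims:
        if slim.end > len(flags):
            raise ValueError(f"SLiM span [{slim.start},{slim.end}) outside protein")
        if all(flags[slim.start : slim.end]):
            retained.append(slim)
    return retained


def bin_plddt(plddt: float) -> str:
    """Confidence bin for a pLDDT score in [0, 100]."""
    if not 0 <= plddt <= 100:
        raise ValueError(f"pLDDT {plddt} outside [0, 100]")
    if plddt > 90:
        return VERY_HIGH
    if plddt > 70:
        return HIGH
    if plddt > 50:
        return MEDIUM
    return VERY_LOW


def route_predictor(msa_depth: int) -> str:
    """Choose the structure predictor from MSA depth (<30 → alignment-free)."""
    if msa_depth < 1:
        raise ValueError("MSA depth must be ≥1 (the query itself counts)")
    return OMEGAFOLD_LIKE if msa_depth < MSA_DEPTH_CUTOFF else ALPHAFOLD_LIKE


@dataclass(frozen=True)
class StructureConfidence:
    accession: str
    plddt: float
    msa_depth: int

    @property
    def bin(self) -> str:
        return bin_plddt(self.plddt)

    @property
    def predictor(self) -> str:
        return route_predictor(self.msa_depth)


def idr_prevalence(
    classes: dict[str, str], idr_calls: dict[str, list[IdrRegion]]
) -> dict[str, tuple[float, int, int]]:
    """Per-class fraction of proteins with ≥1 IDR.

    ``classes`` maps accession → class label. Returns class →
    (fraction, n_with_idr, n_total); classes with no proteins are absent.
    """
    totals: dict[str, int] = {}
    with_idr: dict[str, int] = {}
    for acc, cls in classes.items():
        totals[cls] = totals.get(cls, 0) + 1
        if idr_calls.get(acc):
            with_idr[cls] = with_idr.get(cls, 0) + 1
    return {
        cls: (with_idr.get(cls, 0) / n, with_idr.get(cls, 0), n)
        for cls, n in totals.items()
    }
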