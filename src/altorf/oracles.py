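"""Independent brute-force oracles used by the synthetic-fixture generator
and the test/acceptance suites.

Each oracle re-derives a result by exhaustive enumeration and deliberately
shares no code with the module it checks: a separate codon table, a
position-by-position ORF scan, an every-threshold FDR sweep, a run-length
scanner and a mutate→resplice→retranslate→diff consequence caller.
"""

from __future__ import annotations

# A second, independently keyed standard genetic code (by first/second/third
# base) so the oracle does not share the production codon dictionary.
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)


def oracle_translate_codon(codon: str) -> str | None:
    """Amino acid for a codon ('*' for stop), None if untranslatable."""
    try:
        i = _BASES.index(codon[0]) * 16 + _BASES.index(codon[1]) * 4 + _BASES.index(codon[2])
    except (ValueError, IndexError):
        return None
    return _AA[i]


def oracle_orf_scan(
    seq: str,
    min_codons: int = 30,
    start_codons: tuple[str, ...] = ("ATG",),
    all_starts: bool = False,
) -> list[tuple[int, int, int, str]]:
    """Brute-force ORF scan testing every (position, frame) pair.

    Returns sorted (frame, start, end, protein) tuples; ``end`` is one past
    the stop codon. By default only the most 5′ start per (frame, stop) is
    kept.
    """
    raw: list[tuple[int, int, int, str]] = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] not in start_codons:
            continue
        # walk forward codon by codon from this putative start
        residues = []
        j = i
        while j + 3 <= len(seq):
            aa = oracle_translate_codon(seq[j : j + 3])
            if aa is None:
                break  # ambiguous codon aborts this ORF
            if aa == "*":
                n_codons = (j + 3 - i) // 3
                if n_codons >= min_codons:
                    raw.append((i % 3, i, j + 3, "".join(residues)))
                break
            residues.append(aa)
            j += 3
    if not all_starts:
        best: dict[tuple[int, int], tuple[int, int, int, str]] = {}
        for frame, start, end, protein in raw:
            key = (frame, end)
            if key not in best or start < best[key][1]:
                best[key] = (frame, start, end, protein)
        raw = list(best.values())
    return sorted(raw, key=lambda x: (x[1], x[2]))


def oracle_idr_regions(flags: list[bool], min_run: int = 29) -> list[tuple[int, int]]:
    """Run-length scan for maximal disordered runs of length ≥ min_run."""
    regions = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if j - i >= min_run:
                regions.append((i, j))
            i = j
        else:
            i += 1
    return regions


def oracle_fdr_filter(
    psms: list[tuple[float, bool]], fdr_max: float
) -> set[int]:
    """Exhaustive-threshold FDR filter.

    ``psms`` are (score, is_decoy) pairs; returns the indices of accepted
    targets under the most permissive score cutoff with FDR < fdr_max.
    """
    scores = sorted({s for s, _ in psms})
    best_threshold = None
    for threshold in scores:
        targets = sum(1 for s, d in psms if s >= threshold and not d)
        decoys = sum(1 for s, d in psms if s >= threshold and d)
        if targets > 0 and decoys / targets < fdr_max:
            best_threshold = threshold
            break  # ascending scan: first passing cutoff is most permissive
    if best_threshold is None:
        return set()
    return {
        i for i, (s, d) in enumerate(psms) if s >= best_threshold and not d
    }


def _blosum62() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    letters = m.alphabet
    return {
        (a, b): float(m[a, b]) for a in letters for b in letters
    }


_B62: dict[tuple[str, str], float] | None = None


def gotoh_local(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> tuple[float, float, float]:
    """Quadratic affine-gap Smith–Waterman (Gotoh) with traceback.

    Returns (score, identity, coverage-of-shorter) for the best local
    alignment under BLOSUM62; a gap of length L costs open + (L-1)*extend.
    Written as an independent check of the production aligner.
    """
    global _B62
    if _B62 is None:
        _B62 = _blosum62()
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0, 0.0, 0.0
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 1=M from M, 2=from Ix, 3=from Iy
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            s = _B62.get((ai, b[j - 1]), -4.0)
            prev = M[i - 1][j - 1]
            p = 1
            if Ix[i - 1][j - 1] > prev:
                prev, p = Ix[i - 1][j - 1], 2
            if Iy[i - 1][j - 1] > prev:
                prev, p = Iy[i - 1][j - 1], 3
            val = prev + s
            if val <= 0:
                M[i][j], ptr[i][j] = 0.0, 0
            else:
                M[i][j], ptr[i][j] = val, p
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best <= 0:
        return 0.0, 0.0, 0.0
    # traceback: state M takes a diagonal (aligned-pair) step; Ix/Iy walk
    # back through the gap run until it reopens from M
    i, j, state = bi, bj, "M"
    matches = pairs = 0
    while i > 0 and j > 0:
        if state == "M":
            if ptr[i][j] == 0 and M[i][j] == 0:
                break
            pairs += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            p = ptr[i][j]
            i, j = i - 1, j - 1
            state = {1: "M", 2: "Ix", 3: "Iy", 0: "END"}[p]
            if state == "END":
                break
        elif state == "Ix":
            came_from_m = M[i - 1][j] - gap_open >= Ix[i - 1][j] - gap_extend
            i -= 1
            state = "M" if came_from_m else "Ix"
        else:  # Iy
            came_from_m = M[i][j - 1] - gap_open >= Iy[i][j - 1] - gap_extend
            j -= 1
            state = "M" if came_from_m else "Iy"
    return best, matches / pairs, pairs / min(n, m)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_project_edit(
    genomic_positions: list[int],
    strand: str,
    pos: int,
    ref: str,
    alt: str,
) -> tuple[int, str, str] | None:
    """Project a genomic replacement into transcript space by position lookup.

    ``genomic_positions`` lists the genomic coordinate of every transcript
    base, 5′→3′. Returns (t_pos, ref_t, alt_t) or None when any edited base
    is not exonic or the edited bases are not contiguous in the transcript.
    """
    index = {g: i for i, g in enumerate(genomic_positions)}
    t_positions = []
    for g in range(pos, pos + len(ref)):
        if g not in index:
            return None
        t_positions.append(index[g])
    lo, hi = min(t_positions), max(t_positions)
    if hi - lo + 1 != len(ref):
        return None
    if strand == "+":
        return lo, ref, alt
    rc = lambda s: "".join(_COMP[b] for b in reversed(s))
    return lo, rc(ref), rc(alt)


def oracle_variant_consequence(
    t_seq: str,
    orf_start: int,
    orf_end: int,
    edit: tuple[int, str, str] | None,
    start_codons: tuple[str, ...] = ("ATG",),
) -> str:
    """Mutate → retranslate → diff consequence categorisation for one ORF.

    ``edit`` is the transcript-space (position, ref, alt) replacement, or
    None when the variant does not project cleanly into the transcript
    (intronic / boundary-spanning), which yields ``non_orf``.
    """
    if edit is None:
        return "non_orf"
    pos, ref, alt = edit
    lo, hi = pos, pos + len(ref)
    if hi <= orf_start or lo >= orf_end:
        return "non_orf"
    assert t_seq[lo:hi] == ref
    mutated = t_seq[:lo] + alt + t_seq[hi:]
    if lo < orf_start + 3 and mutated[orf_start : orf_start + 3] not in start_codons:
        return "start_lost"
    if (len(alt) - len(ref)) % 3 != 0:
        return "frameshift"
    # translate original and mutated from the ORF start to the first stop
    def _protein(seq: str) -> str:
        out = []
        for p in range(orf_start, len(seq) - 2, 3):
            aa = oracle_translate_codon(seq[p : p + 3])
            if aa is None or aa == "*":
                break
            out.append(aa)
        return "".join(out)

    old, new = _protein(t_seq), _protein(mutated)
    if len(alt) > len(ref):
        return "inframe_insertion"
    if len(alt) < len(ref):
        return "inframe_deletion"
    if new == old:
        return "synonymous"
    if len(new) < len(old):
        return "stop_gained"
    if len(new) > len(old):
        return "stop_lost"
    return "missense"
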