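"""Independent brute-force oracles used by the tests.

Deliberately naive re-implementations (per-position loops, interval
arithmetic) kept separate from the package code paths they check.  The
IUPAC table comes from Biopython so even the alphabet definition is an
independent source.
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

# Biopython's table maps e.g. "W" -> "AT"; read bases must be called bases.
IUPAC_ORACLE = {code: set(bases) for code, bases in ambiguous_dna_values.items()}


def oracle_site_mismatches(pattern: str, window: str) -> int:
    mm = 0
    for p, b in zip(pattern, window):
        if b == "N" or b not in IUPAC_ORACLE[p]:
            mm += 1
    return mm


def oracle_find_matches(seq: str, pattern: str) -> list[int]:
    """All start positions where the pattern matches exactly (overlaps kept)."""
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if oracle_site_mismatches(pattern, seq[i : i + len(pattern)]) == 0:
            hits.append(i)
    return hits


def oracle_revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
            "W": "W", "S": "S", "R": "Y", "Y": "R", "K": "M", "M": "K",
            "B": "V", "V": "B", "D": "H", "H": "D", "U": "A"}
    return "".join(comp[c] for c in reversed(seq))


def oracle_cut_positions(seq: str, pattern: str, cut_offset: int) -> list[int]:
    """Top-strand cut positions from both strands, deduplicated."""
    positions = {m + cut_offset for m in oracle_find_matches(seq, pattern)}
    rc = oracle_revcomp(pattern)
    if not all(IUPAC_ORACLE[a] == IUPAC_ORACLE[b] for a, b in zip(pattern, rc)):
        rc_offset = len(pattern) - cut_offset
        positions.update(
            m + rc_offset for m in oracle_find_matches(seq, rc)
        )
    return sorted(p for p in positions if 0 <= p <= len(seq))


def oracle_fragments(seq_len: int, cuts: list[int]) -> list[tuple[int, int]]:
    bounds = [0] + [c for c in cuts if 0 < c < seq_len] + [seq_len]
    return [
        (a, b) for a, b in zip(bounds, bounds[1:]) if b > a
    ]


def oracle_digest(
    seq: str, pattern: str, cut_offset: int, min_len: int, max_len: int
) -> dict:
    """Cut positions, all fragments and size-selected interior fragments."""
    cuts = oracle_cut_positions(seq, pattern, cut_offset)
    frags = oracle_fragments(len(seq), cuts)
    interior = [
        (a, b)
        for (a, b) in frags
        if a in cuts and b in cuts and min_len <= b - a <= max_len
    ]
    return {"cuts": cuts, "fragments": frags, "in_range": interior}
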