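"""Self-correcting, variable-length in-line barcode design.

Barcodes are nucleotide Hamming(15,11) codewords.  Each nucleotide is mapped
to two bits (A=00, C=01, G=10, T=11) and the two bit planes are encoded
independently with the binary Hamming(15,11) code (parity bits at positions
1, 2, 4 and 8, 1-based).  Because each plane has minimum distance 3, any two
distinct codewords differ in at least three nucleotide positions, and a
single nucleotide substitution (one or two bit flips at one position) is
corrected by per-plane syndrome decoding.

Experimental barcodes are shorter than the 15-nucleotide frame: the trailing
data positions of the codeword are forced to A (poly-A padding) and then cut
off, so re-appending A restores a valid codeword and the self-correcting
property survives truncation down to 8 nt (position 8 is the last parity
bit).  Length-16 barcodes extend a full 15-frame codeword by one extra base;
they carry no algebraic guarantee, so every set-level constraint is enforced
on them by explicit checking.

Set-level constraints (all relative to the enzyme the set is designed for):
no barcode contains a recognition-site match, nor creates one at its junction
with the restriction remnant; no barcode is a prefix of another barcode's
(sequence + recognition site) string; and every pair of (barcode +
recognition site) strings differs in >= 3 positions over their shared prefix.
The generator additionally balances nucleotide usage per sequencing cycle to
protect cluster calling on low-diversity libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Iterable, Sequence

from .enzymes import IUPAC, Enzyme, iupac_compatible

__all__ = [
    "Barcode",
    "BarcodeSet",
    "BarcodeDesignError",
    "encode_hamming",
    "decode_hamming",
    "combined_distance",
    "generate_barcodes",
    "validate_barcode_set",
    "write_barcode_file",
    "read_barcode_file",
]

_NUCS = "ACGT"
_NUC_TO_BITS = {"A": (0, 0), "C": (0, 1), "G": (1, 0), "T": (1, 1)}
_BITS_TO_NUC = {v: k for k, v in _NUC_TO_BITS.items()}

#: 1-based codeword positions of parity and data bits in Hamming(15,11)
PARITY_POSITIONS = (1, 2, 4, 8)
DATA_POSITIONS = (3, 5, 6, 7, 9, 10, 11, 12, 13, 14, 15)

FRAME_LENGTH = 15
DATA_LENGTH = 11


class BarcodeDesignError(RuntimeError):
    """Raised when the constraint solver cannot complete a barcode set."""


# ---------------------------------------------------------------------------
# binary Hamming(15,11), one bit plane


def _encode_plane(data_bits: Sequence[int]) -> list[int]:
    word = [0] * (FRAME_LENGTH + 1)  # 1-based
    for pos, bit in zip(DATA_POSITIONS, data_bits):
        word[pos] = bit
    for p in PARITY_POSITIONS:
        word[p] = 0
        parity = 0
        for pos in range(1, FRAME_LENGTH + 1):
            if pos != p and (pos & p) and word[pos]:
                parity ^= 1
        word[p] = parity
    return word[1:]


def _decode_plane(word_bits: Sequence[int]) -> tuple[list[int], int]:
    """Syndrome-decode one plane; returns (data bits, corrected position or 0)."""
    word = list(word_bits)
    syndrome = 0
    for pos in range(1, FRAME_LENGTH + 1):
        if word[pos - 1]:
            syndrome ^= pos
    if syndrome:
        word[syndrome - 1] ^= 1
    return [word[pos - 1] for pos in DATA_POSITIONS], syndrome


def encode_hamming(data: str) -> str:
    """Encode 11 data nucleotides into a 15-nucleotide codeword."""
    if len(data) != DATA_LENGTH:
        raise ValueError(f"data must be {DATA_LENGTH} nt, got {len(data)}")
    planes = []
    for plane in (0, 1):
        try:
            bits = [_NUC_TO_BITS[c][plane] for c in data]
        except KeyError:
            raise ValueError(f"data must be over ACGT: {data!r}") from None
        planes.append(_encode_plane(bits))
    return "".join(
        _BITS_TO_NUC[(planes[0][i], planes[1][i])] for i in range(FRAME_LENGTH)
    )


def decode_hamming(word: str) -> tuple[str, set[int]]:
    """Decode a 15-nucleotide word, correcting one substitution per plane.

    ``N`` bases are treated as A and flagged as corrections.  Returns the 11
    data nucleotides and the (1-based) positions where a correction was made.
    """
    if len(word) != FRAME_LENGTH:
        raise ValueError(f"word must be {FRAME_LENGTH} nt, got {len(word)}")
    corrected: set[int] = set()
    cleaned = []
    for i, c in enumerate(word, 1):
        if c == "N":
            corrected.add(i)
            c = "A"
        elif c not in _NUC_TO_BITS:
            raise ValueError(f"word must be over ACGTN: {word!r}")
        cleaned.append(c)
    data_planes = []
    for plane in (0, 1):
        bits = [_NUC_TO_BITS[c][plane] for c in cleaned]
        data_bits, syndrome = _decode_plane(bits)
        if syndrome:
            corrected.add(syndrome)
        data_planes.append(data_bits)
    data = "".join(
        _BITS_TO_NUC[(data_planes[0][i], data_planes[1][i])]
        for i in range(DATA_LENGTH)
    )
    return data, corrected


# ---------------------------------------------------------------------------
# barcodes and barcode sets


@dataclass(frozen=True)
class Barcode:
    sequence: str

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set(_NUCS):
            raise ValueError(f"barcode must be over ACGT: {self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codeword_frame(self) -> str | None:
        """The poly-A padded 15 nt frame, or None for length-16 barcodes."""
        if len(self.sequence) > FRAME_LENGTH:
            return None
        return self.sequence + "A" * (FRAME_LENGTH - len(self.sequence))


@dataclass
class BarcodeSet:
    barcodes: list[Barcode]
    enzyme: Enzyme

    def sequences(self) -> list[str]:
        return [b.sequence for b in self.barcodes]

    def __len__(self) -> int:
        return len(self.barcodes)


def combined_distance(b1: Barcode | str, b2: Barcode | str, enzyme: Enzyme) -> int:
    """Prefix-aligned distance between two (barcode + recognition) strings.

    The two strings are compared over their shared prefix; a position where
    either side carries a degenerate IUPAC code counts as a mismatch only if
    the expansions are disjoint (worst case: degeneracy never adds distance).
    This is the separation that matters for left-to-right demultiplexing.
    """
    s1 = (b1.sequence if isinstance(b1, Barcode) else b1) + enzyme.recognition
    s2 = (b2.sequence if isinstance(b2, Barcode) else b2) + enzyme.recognition
    return sum(
        not iupac_compatible(a, b)
        for a, b in zip(s1, s2)
    )


def _pattern_possible_at(text: str, pattern: str, start: int) -> bool:
    """Can ``pattern`` match ``text`` at ``start``, where text may itself
    contain IUPAC codes (compatible-expansion semantics)?"""
    if start + len(pattern) > len(text):
        return False
    return all(
        iupac_compatible(pattern[i], text[start + i]) for i in range(len(pattern))
    )


def _contains_site(barcode_seq: str, enzyme: Enzyme) -> bool:
    """Site inside the barcode, or created at the barcode/site junction."""
    joined = barcode_seq + enzyme.recognition
    pattern = enzyme.recognition
    for start in range(len(joined) - len(pattern) + 1):
        if start == len(barcode_seq):
            continue  # the legitimate ligated site itself
        if _pattern_possible_at(joined, pattern, start):
            return True
    return False


def _is_prefix(short: str, long_with_site: str) -> bool:
    return len(short) <= len(long_with_site) and all(
        iupac_compatible(a, b) for a, b in zip(short, long_with_site)
    )


def _violates_set(candidate: str, accepted: Sequence[str], enzyme: Enzyme) -> bool:
    rec = enzyme.recognition
    for other in accepted:
        if combined_distance(candidate, other, enzyme) < 3:
            return True
        if _is_prefix(candidate, other + rec) or _is_prefix(other, candidate + rec):
            return True
    return False


def _random_codeword(rng: Random, target_len: int) -> str:
    """A random codeword whose trailing positions beyond target_len are A."""
    data = [
        "A" if pos > target_len else rng.choice(_NUCS) for pos in DATA_POSITIONS
    ]
    return encode_hamming("".join(data))


def _imbalance(counts: list[dict[str, int]], seq: str) -> int:
    """Per-cycle (max - min) nucleotide count spread if ``seq`` were added."""
    score = 0
    for i, c in enumerate(seq):
        col = dict(counts[i]) if i < len(counts) else {n: 0 for n in _NUCS}
        col[c] += 1
        score += max(col.values()) - min(col.values())
    return score


def generate_barcodes(
    n: int,
    enzyme: Enzyme,
    min_len: int = 8,
    max_len: int = 16,
    seed: int | None = None,
    attempts_per_barcode: int = 20000,
    candidates_per_slot: int = 24,
) -> BarcodeSet:
    """Generate ``n`` mutually compatible barcodes for ``enzyme``.

    Target lengths cycle over [min_len, max_len] so the set staggers the
    restriction site across sequencing cycles.  For each slot a pool of valid
    candidates is drawn and the one that best balances per-cycle nucleotide
    usage is kept (greedy).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= min_len <= max_len <= FRAME_LENGTH + 1:
        raise ValueError(f"lengths must satisfy 1 <= min <= max <= {FRAME_LENGTH + 1}")
    rng = Random(seed)
    span = max_len - min_len + 1
    targets = [min_len + (i % span) for i in range(n)]
    accepted: list[str] = []
    counts: list[dict[str, int]] = []
    for target in targets:
        pool: list[str] = []
        for _ in range(attempts_per_barcode):
            frame_len = min(target, FRAME_LENGTH)
            cand = _random_codeword(rng, frame_len)[:frame_len]
            if target == FRAME_LENGTH + 1:
                cand += rng.choice(_NUCS)
            if _contains_site(cand, enzyme):
                continue
            if _violates_set(cand, accepted, enzyme) or cand in pool:
                continue
            pool.append(cand)
            if len(pool) >= candidates_per_slot:
                break
        if not pool:
            raise BarcodeDesignError(
                f"no valid length-{target} barcode found after "
                f"{attempts_per_barcode} attempts; request fewer barcodes or a "
                f"wider length range"
            )
        best = min(pool, key=lambda s: (_imbalance(counts, s), s))
        accepted.append(best)
        for i, c in enumerate(best):
            while i >= len(counts):
                counts.append({nuc: 0 for nuc in _NUCS})
            counts[i][c] += 1
    return BarcodeSet([Barcode(s) for s in accepted], enzyme)


def validate_barcode_set(bset: BarcodeSet) -> list[str]:
    """All constraint violations in a set; an empty list means valid."""
    violations: list[str] = []
    enzyme = bset.enzyme
    rec = enzyme.recognition
    seqs = bset.sequences()
    for s in seqs:
        if _contains_site(s, enzyme):
            violations.append(f"site-content: {s} contains or creates {rec}")
        if len(s) <= FRAME_LENGTH:
            frame = s + "A" * (FRAME_LENGTH - len(s))
            _, corrected = decode_hamming(frame)
            if corrected:
                violations.append(f"codeword: {s} is not a valid padded codeword")
        else:
            _, corrected = decode_hamming(s[:FRAME_LENGTH])
            if corrected:
                violations.append(
                    f"codeword: {s} does not extend a valid 15 nt codeword"
                )
    if len(set(seqs)) != len(seqs):
        violations.append("duplicate barcodes in set")
    for i, s1 in enumerate(seqs):
        for s2 in seqs[i + 1 :]:
            d = combined_distance(s1, s2, enzyme)
            if d < 3:
                violations.append(f"distance: {s1} vs {s2} = {d} < 3")
            if _is_prefix(s1, s2 + rec) or _is_prefix(s2, s1 + rec):
                violations.append(f"prefix: {s1} / {s2}")
    return violations


def write_barcode_file(bset: BarcodeSet, path: str | Path) -> int:
    """Write barcode<TAB>enzyme rows (sample-sheet / simulator input)."""
    with open(path, "wt") as handle:
        for bc in bset.barcodes:
            handle.write(f"{bc.sequence}\t{bset.enzyme.name}\n")
    return len(bset.barcodes)


def read_barcode_file(path: str | Path) -> list[tuple[str, str]]:
    """Read (barcode, enzyme name) rows; the enzyme column may be empty."""
    rows: list[tuple[str, str]] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            rows.append((fields[0].strip().upper(), fields[1].strip() if len(fields) > 1 else ""))
    return rows
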