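"""Restriction enzymes: IUPAC-degenerate recognition sequences and cut offsets.

An enzyme is described by its name, a recognition sequence over the IUPAC
nucleotide alphabet (e.g. ``GCWGC`` for ApeKI, where W = A or T) and a cut
offset: the number of bases 5' of the top-strand cut inside the recognition
sequence.  In annotation files and inline definitions the cut position is
written with a caret, mirroring the conventional ``G^CWGC`` notation; a
missing caret means the enzyme cuts at the very start of its site.

A default annotation file covering the common reduced-representation enzymes
ships with the package; users can override or extend it with their own
tab-delimited file (columns: name, recognition[, remnant], ``#`` comments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "IUPAC",
    "Enzyme",
    "EnzymeTable",
    "EnzymeFileError",
    "iupac_match",
    "iupac_compatible",
    "site_mismatches",
    "parse_enzyme_file",
    "builtin_enzymes",
    "enzyme_from_spec",
]

# IUPAC nucleotide codes and their expansions over {A, C, G, T}
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class EnzymeFileError(ValueError):
    """Raised for malformed enzyme annotation input."""


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff a read base satisfies one IUPAC pattern position.

    An ``N`` in the *read* never satisfies any pattern position (it is a
    failed base call, so it always counts as a mismatch); an ``N`` in the
    *pattern* matches every called base.
    """
    if base == "N":
        return False
    try:
        return base in IUPAC[pattern_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {pattern_char!r}") from None


def iupac_compatible(code1: str, code2: str) -> bool:
    """True iff two IUPAC codes have intersecting expansions (pattern-vs-pattern)."""
    return not IUPAC[code1].isdisjoint(IUPAC[code2])


@lru_cache(maxsize=256)
def compiled_pattern(pattern: str) -> tuple[frozenset[str], ...]:
    """Pattern as a tuple of per-position base sets (for tight scan loops)."""
    return tuple(IUPAC[c] for c in pattern)


def site_mismatches(pattern: str, window: str) -> int:
    """Count positions of ``window`` that fail the IUPAC ``pattern``."""
    if len(pattern) != len(window):
        raise ValueError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    return sum(not iupac_match(p, b) for p, b in zip(pattern, window))


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with recognition pattern and top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int
    remnant: str | None = None  # ligated overhang remnant, when supplied

    def __post_init__(self) -> None:
        if not self.recognition:
            raise EnzymeFileError(f"enzyme {self.name!r}: empty recognition sequence")
        for c in self.recognition:
            if c not in IUPAC:
                raise EnzymeFileError(
                    f"enzyme {self.name!r}: invalid IUPAC code {c!r} in "
                    f"recognition {self.recognition!r}"
                )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeFileError(
                f"enzyme {self.name!r}: cut offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )
        if self.remnant is not None:
            for c in self.remnant:
                if c not in IUPAC:
                    raise EnzymeFileError(
                        f"enzyme {self.name!r}: invalid IUPAC code {c!r} in remnant"
                    )

    def __len__(self) -> int:
        return len(self.recognition)


class EnzymeTable:
    """Name -> Enzyme mapping with case-insensitive lookup."""

    def __init__(self, enzymes: Iterator[Enzyme] | list[Enzyme] = ()) -> None:
        self._by_key: dict[str, Enzyme] = {}
        for enz in enzymes:
            self.add(enz, replace=False)

    def add(self, enzyme: Enzyme, replace: bool = True) -> None:
        key = enzyme.name.upper()
        if not replace and key in self._by_key:
            raise EnzymeFileError(f"duplicate enzyme name {enzyme.name!r}")
        self._by_key[key] = enzyme

    def get(self, name: str) -> Enzyme:
        try:
            return self._by_key[name.upper()]
        except KeyError:
            raise KeyError(f"unknown enzyme {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name.upper() in self._by_key

    def __iter__(self) -> Iterator[Enzyme]:
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)


def _parse_recognition(raw: str, context: str) -> tuple[str, int]:
    """Split a caret-marked recognition string into (pattern, cut_offset)."""
    caret = raw.count("^")
    if caret > 1:
        raise EnzymeFileError(f"{context}: more than one '^' in {raw!r}")
    offset = raw.index("^") if caret else 0
    return raw.replace("^", "").upper(), offset


def _iter_enzyme_lines(lines: Iterator[str], source: str) -> Iterator[Enzyme]:
    seen: set[str] = set()
    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise EnzymeFileError(
                f"{source}: line {lineno}: expected name<TAB>recognition"
            )
        name = fields[0].strip()
        recognition, offset = _parse_recognition(
            fields[1].strip(), f"{source}: line {lineno}"
        )
        remnant = fields[2].strip().upper() if len(fields) > 2 and fields[2].strip() else None
        if name.upper() in seen:
            raise EnzymeFileError(f"{source}: line {lineno}: duplicate name {name!r}")
        seen.add(name.upper())
        try:
            yield Enzyme(name, recognition, offset, remnant)
        except EnzymeFileError as exc:
            raise EnzymeFileError(f"{source}: line {lineno}: {exc}") from None


def builtin_enzymes() -> EnzymeTable:
    """The enzyme table shipped with the package."""
    text = (
        resources.files("gbskit").joinpath("data/enzymes.tsv").read_text()
    )
    return EnzymeTable(_iter_enzyme_lines(iter(text.splitlines()), "builtin"))


def parse_enzyme_file(path: str | Path, include_builtin: bool = True) -> EnzymeTable:
    """Parse an annotation file, layered on top of the built-in defaults.

    File entries override built-in enzymes of the same name; duplicate names
    *within the file* are an error.
    """
    table = builtin_enzymes() if include_builtin else EnzymeTable()
    with open(path) as handle:
        for enz in _iter_enzyme_lines(iter(handle), str(path)):
            table.add(enz, replace=True)
    return table


def enzyme_from_spec(spec: str, table: EnzymeTable | None = None) -> Enzyme:
    """Resolve an enzyme name, or an inline ``NAME:G^CWGC`` definition."""
    if ":" in spec:
        name, raw = spec.split(":", 1)
        recognition, offset = _parse_recognition(raw.strip(), spec)
        return Enzyme(name.strip(), recognition, offset)
    return (table or builtin_enzymes()).get(spec)
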