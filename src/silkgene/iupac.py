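"""IUPAC nucleotide ambiguity codes and exact-degenerate matching."""

from __future__ import annotations

CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}


def code_for(bases) -> str:
    """IUPAC code covering a set of unambiguous bases."""
    key = frozenset(bases)
    if not key <= frozenset("ACGT") or not key:
        raise ValueError(f"not an unambiguous base set: {bases!r}")
    return BASES_TO_CODE[key]


def matches_at(pattern: str, seq: str, pos: int) -> bool:
    """True if the degenerate pattern matches seq starting at pos (exact, no mismatches)."""
    if pos < 0 or pos + len(pattern) > len(seq):
        return False
    for i, code in enumerate(pattern):
        if seq[pos + i] not in CODE_TO_BASES[code]:
            return False
    return True


def find_all(pattern: str, seq: str) -> list[int]:
    """0-based start positions of every exact degenerate match (overlaps allowed)."""
    up = pattern.upper()
    for code in up:
        if code not in CODE_TO_BASES:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
    return [i for i in range(len(seq) - len(up) + 1) if matches_at(up, seq, i)]
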