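"""Small shared helpers: DNA alphabet handling and rounding conventions."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    """True if *seq* contains only A, C, G, T or N (case-sensitive, upper)."""
    return bool(seq) and set(seq) <= DNA_ALPHABET


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero toward +inf.

    Printed integer statistics use this convention (985.04 -> 985, 541.5 -> 542
    would instead be a ceiling; see callers), matching conventional manuscript
    rounding rather than banker's rounding.
    """
    return math.floor(x + 0.5)


def round_half_up_dp(x: float, dp: int) -> float:
    """Half-up rounding to *dp* decimal places."""
    scale = 10**dp
    return math.floor(x * scale + 0.5) / scale


def flip_orient(orient: str) -> str:
    if orient == "+":
        return "-"
    if orient == "-":
        return "+"
    raise ValueError(f"invalid orientation {orient!r}")
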