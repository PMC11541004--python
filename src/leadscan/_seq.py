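"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def interval_midpoint(start: int, end: int) -> float:
    """Midpoint of a 0-based half-open interval."""
    return (start + end) / 2.0


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Nucleotides separating two half-open intervals; 0 if they touch or overlap."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def contains(outer_start: int, outer_end: int, inner_start: int, inner_end: int) -> bool:
    """True iff [inner) lies entirely within [outer)."""
    return outer_start <= inner_start and inner_end <= outer_end
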