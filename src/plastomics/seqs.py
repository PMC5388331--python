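"""Small sequence helpers used throughout the package.

All sequences are uppercase strings over ``{A, C, G, T, N}``.  Coordinates
are 0-based half-open; circular access wraps modulo the sequence length.
"""

from __future__ import annotations

from .errors import ValidationError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODONS = frozenset({"ATG", "GTG"})


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def check_alphabet(seq: str, *, context: str = "sequence") -> None:
    """Reject any character outside A/C/G/T/N (other ambiguity codes too)."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(
            f"{context} contains disallowed characters: {sorted(bad)!r} "
            "(only A, C, G, T, N are accepted)"
        )


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` allowing the window to wrap past the origin.

    ``end`` may exceed ``len(seq)``; ``start`` must lie in ``[0, len)``.
    """
    n = len(seq)
    if not 0 <= start < n:
        raise ValidationError(f"circular slice start {start} outside [0, {n})")
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def gc_percent(seq: str) -> float:
    """G+C percentage over unambiguous bases (N excluded from denominator)."""
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValidationError("sequence has no unambiguous bases")
    return 100.0 * gc / denom


def translate(seq: str) -> str:
    """Translate in frame 0 using the bacterial/plastid code (stops as ``*``).

    Partial trailing codons are ignored.  Only the standard 61 sense codons
    plus the three stops are needed; anything containing N yields ``X``.
    """
    from Bio.Seq import Seq

    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate(table=11))
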