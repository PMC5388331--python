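"""Inversion event descriptions shared by the generator and the detector."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class InversionEvent:
    """An oriented segment reversal with localized breakpoints.

    Coordinates refer to the genome in which the event was applied or
    detected.  Breakpoint labels name the flanking loci, e.g.
    ``"IGS(ndhJ-trnC)"``; ``mediating_repeat`` is ``(label, length)`` when
    the breakpoints fall inside a planted repeat pair.
    """

    name: str
    left_bp: int
    right_bp: int
    size: int
    left_label: str = ""
    right_label: str = ""
    mediating_repeat: tuple[str, int] | None = None
    markers: tuple[str, ...] = field(default_factory=tuple)
    flags: tuple[str, ...] = field(default_factory=tuple)
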