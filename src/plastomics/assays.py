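"""Packaged primer sequences and inversion screening assays.

The two assays follow the published dual-pair logic: one primer pair only
amplifies on the ancestral arrangement (absence pair), the other only after
the segment has been inverted (presence pair).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .seqs import check_alphabet


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for seq in (self.forward, self.reverse):
            check_alphabet(seq, context=f"primer pair {self.name!r}")
            if "N" in seq:
                raise ValidationError(f"primer {self.name!r} contains N")
            if len(seq) < 15:
                raise ValidationError(
                    f"primer in pair {self.name!r} shorter than 15 nt"
                )


@dataclass(frozen=True)
class AssayDefinition:
    inversion: str
    absence_pair: PrimerPair
    presence_pair: PrimerPair
    max_amplicon: int = 3000

    def __post_init__(self):
        if self.absence_pair == self.presence_pair:
            raise ValidationError(
                f"assay {self.inversion!r}: absence and presence pairs "
                "must differ"
            )


#: Published screening primers (5'->3').
PRIMERS: dict[str, str] = {
    "rps4-bef-F": "CAATCAAATAATAGATAGTAAATGGGTTG",
    "ycf3-bef-R": "GGAATTATTCGTAATAATATATTGGCTAC",
    "ycf3-inv-F": "CGTAATAAGATATTGGCTAC",
    "psbI-int-R": "CTCTTTTCATCTTCGGATTC",
    "FGA-ndhJ-F": "CGTTCCCAATGTGCCTAT",
    "FGA-trnF-R": "TGGTAGAGCAGAGGACTG",
    "FGA-trnC-R": "CAAATCCTTTTTCCCCAGTT",
}

INV36_ASSAY = AssayDefinition(
    inversion="INV36",
    absence_pair=PrimerPair(
        "36kb-absence", PRIMERS["rps4-bef-F"], PRIMERS["ycf3-bef-R"]
    ),
    presence_pair=PrimerPair(
        "36kb-presence", PRIMERS["ycf3-inv-F"], PRIMERS["psbI-int-R"]
    ),
)

INV24_ASSAY = AssayDefinition(
    inversion="INV24",
    absence_pair=PrimerPair(
        "24kb-absence", PRIMERS["FGA-ndhJ-F"], PRIMERS["FGA-trnF-R"]
    ),
    presence_pair=PrimerPair(
        "24kb-presence", PRIMERS["FGA-ndhJ-F"], PRIMERS["FGA-trnC-R"]
    ),
)

DEFAULT_ASSAYS = (INV36_ASSAY, INV24_ASSAY)
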