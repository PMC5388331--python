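"""In-silico PCR on circular genomes.

Annealing is a mismatch-count model: a primer binds wherever at most
``max_mismatch`` positions differ and the 3'-terminal ``three_prime_exact``
bases match exactly.  A primer pair yields an amplicon for every convergent
site combination whose product (inclusive of both primers, along the arc
the polymerase actually runs) is at most ``max_len``.  Inversion screening
uses the dual-pair logic: PRESENT iff the presence pair amplifies and the
absence pair does not, ABSENT for the converse, AMBIGUOUS otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import AssayDefinition, DEFAULT_ASSAYS, PrimerPair
from .errors import ConfigError
from .io import PlastomeRecord
from .seqs import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PcrParams:
    max_mismatch: int = 2
    three_prime_exact: int = 3
    max_amplicon: int = 3000

    def __post_init__(self):
        if self.max_mismatch < 0 or self.three_prime_exact < 0:
            raise ConfigError("negative PCR matching parameter")


DEFAULT_PARAMS = PcrParams()


@dataclass(frozen=True)
class PrimerSite:
    position: int  # leftmost plus-strand coordinate of the annealed window
    strand: int    # +1: extends rightward; -1: extends leftward
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    length: int
    start: int  # plus-strand coordinate of the forward-extending site
    end: int    # one past the last base (may exceed n: wraps the origin)
    fwd_site: PrimerSite
    rev_site: PrimerSite


def _mismatch_counts(seq_codes: np.ndarray, primer: str) -> np.ndarray:
    """Mismatches of *primer* laid on the plus strand at every start."""
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    n = len(seq_codes) - len(p) + 1
    counts = np.zeros(n, dtype=np.int32)
    for k in range(len(p)):
        counts += seq_codes[k : n + k] != p[k]
    return counts


def find_primer_sites(
    sequence: str,
    primer: str,
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    circular: bool = True,
) -> list[PrimerSite]:
    """All annealing sites of *primer* on either strand of *sequence*.

    Windows wrapping the origin of a circular sequence are found once.
    """
    L = len(primer)
    if L < three_prime_exact:
        raise ConfigError("primer shorter than the 3'-exact window")
    n = len(sequence)
    ext = sequence + (sequence[: L - 1] if circular and n >= L else "")
    codes = np.frombuffer(ext.encode(), dtype=np.uint8)
    sites: list[PrimerSite] = []
    for strand, laid in ((1, primer), (-1, revcomp(primer))):
        mm = _mismatch_counts(codes, laid)
        # 3' window: rightmost bases for +, leftmost for - (on plus strand)
        w = three_prime_exact
        if w:
            tail = laid[-w:] if strand == 1 else laid[:w]
            off = L - w if strand == 1 else 0
            p = np.frombuffer(tail.encode(), dtype=np.uint8)
            nwin = len(codes) - L + 1
            exact = np.ones(nwin, dtype=bool)
            for k in range(w):
                exact &= codes[off + k : nwin + off + k] == p[k]
        else:
            exact = np.ones(len(codes) - L + 1, dtype=bool)
        hit = np.flatnonzero((mm <= max_mismatch) & exact)
        for pos in hit.tolist():
            if pos >= n:  # duplicate of a wrapped window
                continue
            sites.append(PrimerSite(pos, strand, int(mm[pos])))
    sites.sort(key=lambda s: (s.position, -s.strand))
    return sites


def predict_amplicons(
    sequence: str,
    pair: PrimerPair,
    params: PcrParams = DEFAULT_PARAMS,
    circular: bool = True,
) -> list[Amplicon]:
    """Products of *pair* on *sequence* (each convergent site combination).

    The product runs from a forward-extending site rightward (circularly)
    to the end of a leftward-extending site; divergent sites only amplify
    around the long arc, and only when that arc fits ``max_amplicon``.
    """
    n = len(sequence)
    f_sites = find_primer_sites(
        sequence, pair.forward, params.max_mismatch,
        params.three_prime_exact, circular,
    )
    r_sites = find_primer_sites(
        sequence, pair.reverse, params.max_mismatch,
        params.three_prime_exact, circular,
    )
    out = []
    for fs, rs, flen, rlen in (
        *(
            (a, b, len(pair.forward), len(pair.reverse))
            for a in f_sites if a.strand == 1
            for b in r_sites if b.strand == -1
        ),
        *(
            (b, a, len(pair.reverse), len(pair.forward))
            for a in f_sites if a.strand == -1
            for b in r_sites if b.strand == 1
        ),
    ):
        # fs extends rightward from fs.position; rs ends at rs.position+rlen
        span = (rs.position + rlen) - fs.position
        if circular:
            span %= n
            if span == 0:
                continue
        elif span <= 0:
            continue
        if span < max(flen, rlen):  # primers overlapping nonsensically
            continue
        if span <= params.max_amplicon:
            out.append(
                Amplicon(span, fs.position, fs.position + span, fs, rs)
            )
    out.sort(key=lambda a: (a.length, a.start))
    return out


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

CALLS = ("PRESENT", "ABSENT", "AMBIGUOUS")


@dataclass(frozen=True)
class ScreenCall:
    taxon: str
    inversion: str
    call: str
    absence_lengths: tuple[int, ...]
    presence_lengths: tuple[int, ...]


def screen_inversion(
    record: PlastomeRecord,
    assay: AssayDefinition,
    params: PcrParams | None = None,
) -> ScreenCall:
    params = params or PcrParams(max_amplicon=assay.max_amplicon)
    absent = predict_amplicons(record.sequence, assay.absence_pair, params,
                               record.circular)
    present = predict_amplicons(record.sequence, assay.presence_pair, params,
                                record.circular)
    if present and not absent:
        call = "PRESENT"
    elif absent and not present:
        call = "ABSENT"
    else:
        call = "AMBIGUOUS"
    return ScreenCall(
        taxon=record.id,
        inversion=assay.inversion,
        call=call,
        absence_lengths=tuple(a.length for a in absent),
        presence_lengths=tuple(a.length for a in present),
    )


@dataclass
class ScreenResult:
    calls: pd.DataFrame  # taxon x inversion matrix of PRESENT/ABSENT/...
    details: list[ScreenCall] = field(default_factory=list)
    genus_tally: dict = field(default_factory=dict)
    tribe_tally: dict = field(default_factory=dict)


def run_panel_screen(
    panel: list[tuple[str, PlastomeRecord]],
    assays: tuple[AssayDefinition, ...] = DEFAULT_ASSAYS,
    params: PcrParams | None = None,
    tribes: dict[str, str] | None = None,
) -> ScreenResult:
    """Screen every taxon with every assay.

    ``tribes`` maps taxon name to tribe label for tribe-level tallies;
    genus is the first whitespace-separated token of the taxon name.
    AMBIGUOUS calls are excluded from tallies (with a logged warning).
    """
    details: list[ScreenCall] = []
    rows = {}
    for taxon, record in panel:
        row = {}
        for assay in assays:
            rec = record if record.id == taxon else _renamed(record, taxon)
            call = screen_inversion(rec, assay, params)
            details.append(call)
            row[assay.inversion] = call.call
        rows[taxon] = row
    calls = pd.DataFrame.from_dict(rows, orient="index").reindex(
        [t for t, _ in panel]
    )

    genus_tally: dict[str, set] = {a.inversion: set() for a in assays}
    tribe_tally: dict[str, set] = {a.inversion: set() for a in assays}
    for call in details:
        if call.call == "AMBIGUOUS":
            logger.warning(
                "taxon %s excluded from %s tallies: AMBIGUOUS call",
                call.taxon, call.inversion,
            )
            continue
        if call.call != "PRESENT":
            continue
        genus_tally[call.inversion].add(call.taxon.split()[0])
        if tribes and call.taxon in tribes:
            tribe_tally[call.inversion].add(tribes[call.taxon])
    return ScreenResult(
        calls=calls,
        details=details,
        genus_tally={k: sorted(v) for k, v in genus_tally.items()},
        tribe_tally={k: sorted(v) for k, v in tribe_tally.items()},
    )


def _renamed(record: PlastomeRecord, taxon: str) -> PlastomeRecord:
    return PlastomeRecord(
        taxon, record.sequence, record.circular, list(record.features)
    )


def genera_without_any_inversion(result: ScreenResult) -> list[str]:
    """Genera whose every non-ambiguous call is ABSENT."""
    df = result.calls
    out = []
    for genus, sub in df.groupby(
        [t.split()[0] for t in df.index], sort=True
    ):
        vals = sub.values.ravel()
        if all(v == "ABSENT" for v in vals):
            out.append(genus)
    return out
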