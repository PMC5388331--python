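"""Seeded generation of annotated synthetic plastomes.

The generator emits circular quadripartite genomes (LSC + IRa + SSC + IRb,
with IRb the exact reverse complement of IRa) over a fixed legume-style gene
catalog.  The large single-copy region is laid out around six pinned
breakpoint loci so that three nested inversions can be applied by name:

* ``INV50`` between the intergenic spacers right of trnK-UUU and left of
  accD (realized size ~50 kb at full scale),
* ``INV36`` between a pair of planted 29-bp inverted repeat copies next to
  trnS-GCU and trnS-GGA (~36 kb),
* ``INV24`` between the spacers right of ndhJ and left of petN, i.e. the
  spacers flanked by trnF-GAA and trnC-GCA (~24 kb), nested inside the
  others.

Exact binding sites for the packaged screening primers are planted in the
spacers around the INV36/INV24 breakpoints with orientations such that each
assay's absence pair converges only on the ancestral arrangement and its
presence pair only after the inversion.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .assays import PRIMERS
from .errors import (
    AmbiguityError,
    AnchorResolutionError,
    ConfigError,
    LookupError_,
    SizingError,
    ValidationError,
)
from .events import InversionEvent
from .io import Feature, GENE_KINDS, PlastomeRecord
from .seqs import revcomp

# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneDef:
    """One catalog entry.  ``length`` is the genomic footprint in bp."""

    name: str
    kind: str  # CDS / tRNA / rRNA
    strand: int
    length: int
    region: str  # LSC / SSC / IR
    exon_lengths: tuple[int, ...] | None = None  # coding-strand order
    intron_length: int = 0


@dataclass(frozen=True)
class GeneCatalog:
    entries: tuple[GeneDef, ...]

    def __post_init__(self):
        per_region: dict[str, set[str]] = {}
        for g in self.entries:
            seen = per_region.setdefault(g.region, set())
            if g.name in seen:
                raise ValidationError(
                    f"gene {g.name!r} duplicated in region {g.region}"
                )
            seen.add(g.name)

    def get(self, name: str) -> GeneDef:
        for g in self.entries:
            if g.name == name:
                return g
        raise LookupError_(f"gene {name!r} not in catalog")

    def in_region(self, region: str) -> list[GeneDef]:
        return [g for g in self.entries if g.region == region]

    def cds_count(self) -> int:
        return sum(1 for g in self.entries if g.kind == "CDS")


#: The 71 conserved protein-coding genes plus accD (an LSC anchor locus).
_CDS_LEN_FULL = {
    "accD": 1497,
    "atpA": 1524, "atpB": 1497, "atpE": 402, "atpF": 555, "atpH": 246,
    "atpI": 744, "ccsA": 960, "cemA": 690, "clpP": 591, "matK": 1530,
    "ndhA": 1092, "ndhB": 1533, "ndhC": 363, "ndhD": 1503, "ndhE": 306,
    "ndhF": 2241, "ndhG": 531, "ndhH": 1182, "ndhI": 543, "ndhJ": 477,
    "ndhK": 678, "petA": 963, "petB": 648, "petD": 483, "petG": 114,
    "petL": 96, "petN": 90, "psaA": 2253, "psaB": 2205, "psaC": 246,
    "psaI": 111, "psaJ": 135, "psbA": 1062, "psbB": 1527, "psbC": 1386,
    "psbD": 1062, "psbE": 252, "psbF": 120, "psbH": 222, "psbI": 111,
    "psbJ": 123, "psbK": 186, "psbL": 117, "psbM": 105, "psbN": 132,
    "psbT": 108, "psbZ": 189, "rbcL": 1428, "rpl2": 825, "rpl14": 369,
    "rpl16": 408, "rpl20": 354, "rpl23": 282, "rpl32": 174, "rpl33": 201,
    "rpl36": 114, "rpoA": 1014, "rpoB": 3213, "rpoC1": 2055, "rpoC2": 4155,
    "rps2": 711, "rps3": 657, "rps4": 606, "rps7": 468, "rps8": 405,
    "rps11": 417, "rps12": 372, "rps14": 303, "rps15": 273, "rps19": 279,
    "ycf3": 507,
}

_RRNA_LEN_FULL = {"rrn16": 1491, "rrn23": 2810, "rrn4.5": 103, "rrn5": 121}
_RRNA_LEN_MINI = {"rrn16": 120, "rrn23": 150, "rrn4.5": 60, "rrn5": 60}

_IR_CDS = ("rpl23", "rpl2", "rps7", "ndhB")
_SSC_CDS = (
    "ndhF", "rpl32", "ccsA", "ndhD", "psaC", "ndhE", "ndhG", "ndhI",
    "ndhA", "ndhH",
)

_LSC_TRNAS = (
    "trnH-GUG", "trnK-UUU", "trnQ-UUG", "trnG-GCC", "trnS-GCU", "trnF-GAA",
    "trnT-GGU", "trnC-GCA", "trnM-CAU", "trnS-GGA",
)
_SSC_TRNAS = ("trnL-UAG",)
_IR_TRNAS = ("trnL-CAA", "trnI-GAU", "trnA-UGC", "trnR-ACG", "trnN-GUU")

_MINUS_GENES = {"psbA", "rps16", "ndhF", "ndhB"}

#: 29-bp motif planted (as an inverted pair) at the INV36 breakpoints.
REPEAT29 = "ATCGGCCATAGTTCAGAGGTTAGAACGGC"
REPEAT_LABEL = "repeat29"

#: Offset (codon-aligned) of the planted "AAAC" motif inside rps16 exon2.
_AAAC_EXON2_CODON = 12


def default_gene_catalog(profile: str = "full") -> GeneCatalog:
    """Catalog of 72 CDS (71 conserved + rps16), tRNAs and rRNAs.

    ``profile="mini"`` shrinks every gene so a ~21-kb genome can hold the
    complete order; names, strands, regions and anchors are identical.
    """
    if profile not in ("full", "mini"):
        raise ConfigError(f"unknown profile {profile!r}")
    mini = profile == "mini"

    def cds_len(name: str) -> int:
        return 72 if mini else _CDS_LEN_FULL[name]

    trna_len = 60 if mini else 74
    entries: list[GeneDef] = []

    def add(name, kind, region, length=None, **kw):
        strand = -1 if name in _MINUS_GENES else 1
        if length is None:
            length = cds_len(name) if kind == "CDS" else trna_len
        entries.append(GeneDef(name, kind, strand, length, region, **kw))

    for name in _CDS_LEN_FULL:
        if name in _IR_CDS:
            region = "IR"
        elif name in _SSC_CDS:
            region = "SSC"
        else:
            region = "LSC"
        add(name, "CDS", region)
    exons = (42, 120) if mini else (90, 240)
    intron = 240 if mini else 850
    add(
        "rps16", "CDS", "LSC", length=sum(exons) + intron,
        exon_lengths=exons, intron_length=intron,
    )
    for name in _LSC_TRNAS:
        add(name, "tRNA", "LSC")
    for name in _SSC_TRNAS:
        add(name, "tRNA", "SSC")
    for name in _IR_TRNAS:
        add(name, "tRNA", "IR")
    rrn = _RRNA_LEN_MINI if mini else _RRNA_LEN_FULL
    for name, length in rrn.items():
        add(name, "rRNA", "IR", length=length)
    return GeneCatalog(tuple(entries))


# ---------------------------------------------------------------------------
# Region lengths / profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionLengths:
    lsc: int
    ssc: int
    ir: int

    @property
    def total(self) -> int:
        return self.lsc + self.ssc + 2 * self.ir


FULL_REGIONS = RegionLengths(lsc=85140, ssc=18413, ir=25494)
MINI_REGIONS = RegionLengths(lsc=14000, ssc=2600, ir=2200)


def regions_for_profile(profile: str) -> RegionLengths:
    if profile == "full":
        return FULL_REGIONS
    if profile == "mini":
        return MINI_REGIONS
    raise ConfigError(f"unknown profile {profile!r}")


# ---------------------------------------------------------------------------
# LSC layout plan
# ---------------------------------------------------------------------------

# Breakpoint positions as fractions of the LSC length.  Chosen so the three
# nested segments measure ~50/36/24 kb at full scale and all six breakpoints
# are pairwise distinct and interior to the LSC.
_FRAC = {
    "bp50L": 5.0 / 85.0,
    "R1": 13.0 / 85.0,
    "bp24L": 16.0 / 85.0,
    "bp24R": 40.0 / 85.0,
    "R2": 49.0 / 85.0,
    "bp50R": 55.0 / 85.0,
}

# Plan items, in ancestral genomic order.  ("gene", name) items are fillers
# distributed evenly between pins; pins fix a gene edge or a motif start at
# anchor + offset (offset in units of u).
_LSC_PLAN: list[tuple] = [
    ("gene", "trnH-GUG"),
    ("gene", "psbA"),
    ("pin_gene", "trnK-UUU", "bp50L", -1.2, "end"),
    ("pin_gene", "matK", "bp50L", +1.2, "start"),
    ("gene", "rps16"),
    ("gene", "trnQ-UUG"),
    ("gene", "psbK"),
    ("gene", "trnG-GCC"),
    ("pin_gene", "psbI", "R1", -1.5, "end"),
    ("motif", "site:psbI-int-R", "psbI-int-R", +1, "R1", -1.2),
    ("repeat", REPEAT_LABEL, +1, "R1"),
    ("pin_gene", "trnS-GCU", "R1", +0.3, "start"),
    ("pin_gene", "ndhJ", "bp24L", -1.2, "end"),
    ("motif", "site:FGA-ndhJ-F", "FGA-ndhJ-F", +1, "bp24L", -0.8),
    ("motif", "site:FGA-trnF-R", "FGA-trnF-R", -1, "bp24L", +0.5),
    ("pin_gene", "trnF-GAA", "bp24L", +1.2, "start"),
    ("gene", "rbcL"), ("gene", "atpB"), ("gene", "atpE"),
    ("gene", "psbE"), ("gene", "psbF"), ("gene", "psbJ"), ("gene", "psbL"),
    ("gene", "petA"), ("gene", "petG"), ("gene", "petL"), ("gene", "cemA"),
    ("gene", "psbB"), ("gene", "psbH"), ("gene", "psbN"), ("gene", "psbT"),
    ("gene", "petB"), ("gene", "petD"), ("gene", "rpoA"), ("gene", "rps11"),
    ("gene", "rpl36"), ("gene", "rps8"), ("gene", "rpl14"), ("gene", "rpl16"),
    ("gene", "rps3"), ("gene", "rps19"), ("gene", "atpA"), ("gene", "atpF"),
    ("gene", "atpH"), ("gene", "atpI"), ("gene", "rps2"), ("gene", "ndhC"),
    ("gene", "ndhK"), ("gene", "trnT-GGU"),
    ("pin_gene", "trnC-GCA", "bp24R", -1.2, "end"),
    ("motif", "site:FGA-trnC-R", "FGA-trnC-R", +1, "bp24R", -0.5),
    ("pin_gene", "petN", "bp24R", +1.2, "start"),
    ("gene", "psbM"), ("gene", "psbZ"), ("gene", "psaJ"), ("gene", "rps14"),
    ("gene", "rpl33"), ("gene", "rpl20"), ("gene", "rps12"), ("gene", "clpP"),
    ("gene", "trnM-CAU"),
    ("pin_gene", "ycf3", "R2", -3.0, "end"),
    ("pin_gene", "trnS-GGA", "R2", -1.5, "end"),
    ("motif", "site:ycf3-bef-R", "ycf3-bef-R", +1, "R2", -1.2),
    ("motif", "site:ycf3-inv-F", "ycf3-inv-F", +1, "R2", -0.7),
    ("repeat", REPEAT_LABEL, -1, "R2"),
    ("motif", "site:rps4-bef-F", "rps4-bef-F", -1, "R2", +0.8),
    ("pin_gene", "rps4", "R2", +1.5, "start"),
    ("pin_gene", "psaI", "bp50R", -1.2, "end"),
    ("pin_gene", "accD", "bp50R", +1.2, "start"),
    ("gene", "psbD"), ("gene", "psbC"), ("gene", "rpoB"), ("gene", "rpoC1"),
    ("gene", "rpoC2"), ("gene", "rps15"), ("gene", "psaA"), ("gene", "psaB"),
]

_SSC_ORDER = (
    "ndhF", "rpl32", "trnL-UAG", "ccsA", "ndhD", "psaC", "ndhE", "ndhG",
    "ndhI", "ndhA", "ndhH",
)
_IR_ORDER = (
    "rpl23", "rpl2", "rps7", "ndhB", "trnL-CAA", "rrn16", "trnI-GAU",
    "trnA-UGC", "rrn23", "rrn4.5", "rrn5", "trnR-ACG", "trnN-GUU",
)

_MIN_GAP = 8  # minimum spacer between placed elements, bp


# ---------------------------------------------------------------------------
# Sequence synthesis helpers
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + TAA, exactly *length* bp (multiple of 3)."""
    if length % 3 or length < 9:
        raise ValidationError(f"CDS length {length} not a multiple of 3 >= 9")
    ncod = length // 3 - 2
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), ncod)
    )
    return "ATG" + body + "TAA"


def _rps16_coding(rng: np.random.Generator, exon_lengths) -> str:
    """Coding sequence with a codon-aligned 'AAAC' planted in exon2."""
    total = sum(exon_lengths)
    coding = _random_orf(rng, total)
    k = exon_lengths[0] + 3 * _AAAC_EXON2_CODON
    # codon-aligned AAAC -> codons AAA + C.. ; neither can become a stop
    coding = coding[:k] + "AAAC" + coding[k + 4:]
    assert len(coding) == total
    return coding


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _margin_unit(lsc_len: int) -> int:
    return max(50, round(lsc_len * 500 / 85140))


def _layout_lsc(catalog, lsc_len, rng, gc):
    """Place the LSC plan; returns (sequence, features)."""
    u = _margin_unit(lsc_len)
    anchors = {k: round(f * lsc_len) for k, f in _FRAC.items()}

    # first pass: resolve target (start, length, payload) for every item
    placed: list[dict] = []  # each: {start, length, build(...)}
    pending: list[tuple] = []  # filler genes awaiting distribution
    cursor = _MIN_GAP

    def item_length(it) -> int:
        if it[0] in ("gene", "pin_gene"):
            return catalog.get(it[1]).length
        if it[0] == "motif":
            return len(PRIMERS[it[2]])
        if it[0] == "repeat":
            return len(REPEAT29)
        raise AssertionError(it)

    def flush_fillers(up_to: int):
        nonlocal cursor
        if not pending:
            return
        need = sum(item_length(it) for it in pending)
        free = up_to - cursor - need
        if free < _MIN_GAP * (len(pending) + 1):
            raise SizingError(
                f"LSC too small: {len(pending)} fillers need "
                f"{need + _MIN_GAP * (len(pending) + 1)} bp before position "
                f"{up_to}, only {up_to - cursor} available "
                f"(deficit {_MIN_GAP * (len(pending) + 1) - free} bp)"
            )
        gap = free // (len(pending) + 1)
        for it in pending:
            cursor += gap
            placed.append({"item": it, "start": cursor})
            cursor += item_length(it)
        pending.clear()

    for it in _LSC_PLAN:
        if it[0] == "gene":
            pending.append(it)
            continue
        length = item_length(it)
        if it[0] == "pin_gene":
            _, name, anchor, off, align = it
            pos = anchors[anchor] + round(off * u)
            start = pos - length if align == "end" else pos
        elif it[0] == "motif":
            _, label, key, strand, anchor, off = it
            start = anchors[anchor] + round(off * u)
        else:  # repeat
            _, label, strand, anchor = it
            start = anchors[anchor] - length // 2
        flush_fillers(start - _MIN_GAP)
        if start < cursor + _MIN_GAP:
            raise SizingError(
                f"pinned item {it[1]!r} at {start} overlaps previous "
                f"element ending at {cursor}"
            )
        placed.append({"item": it, "start": start})
        cursor = start + length
    flush_fillers(lsc_len - _MIN_GAP)
    if cursor > lsc_len:
        raise SizingError(f"LSC layout overran region ({cursor} > {lsc_len})")

    # second pass: write sequence + features
    seq = bytearray(_random_bases(rng, lsc_len, gc).encode())
    features: list[Feature] = []

    def write(start: int, s: str):
        seq[start:start + len(s)] = s.encode()

    for p in placed:
        it, start = p["item"], p["start"]
        if it[0] in ("gene", "pin_gene"):
            g = catalog.get(it[1])
            _write_gene(write, features, g, start, rng, gc)
        elif it[0] == "motif":
            _, label, key, strand, _, _ = it
            motif = PRIMERS[key]
            write(start, motif if strand == 1 else revcomp(motif))
            features.append(
                Feature(label, "IGS_label", strand,
                        ((start, start + len(motif)),))
            )
        else:  # repeat
            _, label, strand, _ = it
            write(start, REPEAT29 if strand == 1 else revcomp(REPEAT29))
            features.append(
                Feature(label, "IGS_label", strand,
                        ((start, start + len(REPEAT29)),))
            )
    return seq.decode(), features


def _write_gene(write, features, g: GeneDef, start: int, rng, gc):
    if g.exon_lengths:  # spliced CDS (rps16-style, 2 exons + 1 intron)
        e1, e2 = g.exon_lengths
        coding = _rps16_coding(rng, g.exon_lengths)
        intron_seq = _random_bases(rng, g.intron_length, gc)
        if g.strand == 1:
            p1 = (start, start + e1)
            pi = (p1[1], p1[1] + g.intron_length)
            p2 = (pi[1], pi[1] + e2)
            write(p1[0], coding[:e1])
            write(pi[0], intron_seq)
            write(p2[0], coding[e1:])
            parts = (p1, p2)
        else:
            # transcription right->left: genomic = rc(exon2)+rc(intron)+rc(exon1)
            p2 = (start, start + e2)
            pi = (p2[1], p2[1] + g.intron_length)
            p1 = (pi[1], pi[1] + e1)
            write(p2[0], revcomp(coding[e1:]))
            write(pi[0], revcomp(intron_seq))
            write(p1[0], revcomp(coding[:e1]))
            parts = (p1, p2)  # transcription order: exon1 first
        features.append(Feature(g.name, "CDS", g.strand, parts))
        features.append(
            Feature(g.name, "intron", g.strand, (pi,))
        )
        return
    if g.kind == "CDS":
        body = _random_orf(rng, g.length)
        write(start, body if g.strand == 1 else revcomp(body))
    else:
        write(start, _random_bases(rng, g.length, gc))
    features.append(
        Feature(g.name, g.kind, g.strand, ((start, start + g.length),))
    )


def _layout_simple(order, catalog, region_len, rng, gc, region_name):
    genes = [catalog.get(n) for n in order]
    need = sum(g.length for g in genes)
    free = region_len - need
    if free < _MIN_GAP * (len(genes) + 1):
        raise SizingError(
            f"{region_name} region of {region_len} bp cannot hold "
            f"{need} bp of genes (deficit {_MIN_GAP * (len(genes) + 1) - free})"
        )
    gap = free // (len(genes) + 1)
    seq = bytearray(_random_bases(rng, region_len, gc).encode())
    features: list[Feature] = []

    def write(start, s):
        seq[start:start + len(s)] = s.encode()

    cursor = 0
    for g in genes:
        cursor += gap
        _write_gene(write, features, g, cursor, rng, gc)
        cursor += g.length
    return seq.decode(), features


def generate_plastome(
    catalog: GeneCatalog,
    region_lengths: RegionLengths = FULL_REGIONS,
    seed: int = 0,
    gc: float = 0.365,
) -> PlastomeRecord:
    """Generate one circular annotated plastome.

    The record is LSC + IRa + SSC + IRb with IRb the exact reverse
    complement of IRa; junction bases are adjusted so the planted repeat is
    maximal (extension by one base breaks the equality).
    """
    rng = np.random.default_rng(seed)
    lsc_seq, lsc_feats = _layout_lsc(catalog, region_lengths.lsc, rng, gc)
    ira_seq, ira_feats = _layout_simple(
        _IR_ORDER, catalog, region_lengths.ir, rng, gc, "IR"
    )
    ssc_seq, ssc_feats = _layout_simple(
        _SSC_ORDER, catalog, region_lengths.ssc, rng, gc, "SSC"
    )

    L, I, S = region_lengths.lsc, region_lengths.ir, region_lengths.ssc
    irb_seq = revcomp(ira_seq)
    features = list(lsc_feats)
    features += [f.shifted(L) for f in ira_feats]
    features += [f.shifted(L + I) for f in ssc_feats]
    for f in ira_feats:  # mirror into IRb
        parts = tuple(
            (L + I + S + (I - e), L + I + S + (I - s)) for s, e in f.parts
        )
        features.append(Feature(f.gene, f.kind, -f.strand, parts))

    seq = bytearray((lsc_seq + ira_seq + ssc_seq + irb_seq).encode())
    n = len(seq)
    assert n == region_lengths.total

    comp = {65: 84, 84: 65, 67: 71, 71: 67}  # A<->T, C<->G on byte values

    def break_extension(i: int, j: int):
        # ensure seq[i] != complement(seq[j]); both indices fall in spacers
        if seq[i] == comp.get(seq[j], 0):
            seq[i] = 65 if seq[i] != 65 else 67
    break_extension(0, L - 1)           # left of IRa vs right of IRb
    break_extension(L + I + S - 1, L + I)  # right of IRa vs left of IRb

    record = PlastomeRecord(
        id=f"synthetic-{seed}",
        sequence=seq.decode(),
        circular=True,
        features=features,
    )
    return record.sorted_copy()


# ---------------------------------------------------------------------------
# Inversions
# ---------------------------------------------------------------------------

Anchor = tuple  # ("igs", gene, "left"/"right") or ("repeat", label)


@dataclass(frozen=True)
class InversionSpec:
    name: str
    left_anchor: Anchor
    right_anchor: Anchor
    approx_size: int = 0


INV50 = InversionSpec(
    "INV50", ("igs", "trnK-UUU", "right"), ("igs", "accD", "left"), 50000
)
INV36 = InversionSpec(
    "INV36", ("repeat", REPEAT_LABEL), ("repeat", REPEAT_LABEL), 36000
)
INV24 = InversionSpec(
    "INV24", ("igs", "ndhJ", "right"), ("igs", "petN", "left"), 24000
)

PRESET_INVERSIONS = {"INV50": INV50, "INV36": INV36, "INV24": INV24}


def _unique_gene(record: PlastomeRecord, name: str) -> Feature:
    feats = record.features_named(name)
    if not feats:
        raise AnchorResolutionError(f"anchor gene {name!r} absent")
    if len(feats) > 1:
        raise AnchorResolutionError(f"anchor gene {name!r} ambiguous")
    return feats[0]


def _resolve_igs(record: PlastomeRecord, gene: str, side: str) -> int:
    f = _unique_gene(record, gene)
    genes = record.gene_features()
    if side == "right":
        nxt = min(
            (g for g in genes if g.start >= f.end), default=None,
            key=lambda g: g.start,
        )
        if nxt is None:
            raise AnchorResolutionError(f"no gene right of {gene!r}")
        lo, hi = f.end, nxt.start
    elif side == "left":
        prv = max(
            (g for g in genes if g.end <= f.start), default=None,
            key=lambda g: g.end,
        )
        if prv is None:
            raise AnchorResolutionError(f"no gene left of {gene!r}")
        lo, hi = prv.end, f.start
    else:
        raise AnchorResolutionError(f"bad IGS side {side!r}")
    if lo >= hi:
        raise AnchorResolutionError(
            f"empty intergenic spacer beside {gene!r}"
        )
    bp = (lo + hi) // 2
    # nudge off any planted motif so no feature is split
    for lab in record.features:
        if lab.kind != "IGS_label":
            continue
        for s, e in lab.parts:
            if s < bp < e:
                bp = e if e <= hi else s
    return bp


def _resolve_repeats(record: PlastomeRecord, label: str) -> tuple[int, int]:
    labs = [
        f for f in record.features if f.kind == "IGS_label" and f.gene == label
    ]
    if len(labs) != 2:
        raise AnchorResolutionError(
            f"repeat label {label!r}: expected 2 copies, found {len(labs)}"
        )
    first, second = sorted(labs, key=lambda f: f.start)
    d = (first.end - first.start) // 2
    # split the left copy at +d from its start and the right copy at -d
    # from its end: the flip then maps each copy onto itself exactly
    # (the copies are inverted duplicates of one another).
    return first.start + d, second.end - d


def apply_inversion(
    record: PlastomeRecord, spec: InversionSpec
) -> tuple[PlastomeRecord, InversionEvent]:
    """Reverse-complement the segment between the spec's anchors.

    Features wholly inside the segment have order, strand and coordinates
    flipped; applying the same spec twice restores the original gene order.
    """
    if spec.left_anchor[0] == "repeat":
        if spec.right_anchor != spec.left_anchor:
            raise AnchorResolutionError(
                "repeat-mediated inversions use the same repeat label for "
                "both anchors"
            )
        l, r = _resolve_repeats(record, spec.left_anchor[1])
    else:
        l = _resolve_igs(record, *spec.left_anchor[1:])
        r = _resolve_igs(record, *spec.right_anchor[1:])
        if l > r:
            l, r = r, l
    if l == r:
        raise AnchorResolutionError(f"{spec.name}: anchors coincide")

    seq = record.sequence
    new_seq = seq[:l] + revcomp(seq[l:r]) + seq[r:]
    new_feats: list[Feature] = []
    for f in record.features:
        inside = all(l <= s and e <= r for s, e in f.parts)
        outside = all(e <= l or s >= r for s, e in f.parts)
        if inside:
            parts = tuple((l + r - e, l + r - s) for s, e in f.parts)
            new_feats.append(replace(f, strand=-f.strand, parts=parts))
        elif outside:
            new_feats.append(f)
        else:
            # Straddling is only legal for planted repeats whose sequence is
            # invariant under the flip (inverted-copy midpoint breakpoints).
            invariant = all(
                new_seq[s:e] == seq[s:e] for s, e in f.parts
            )
            if f.kind == "IGS_label" and invariant:
                new_feats.append(f)
            else:
                raise AnchorResolutionError(
                    f"{spec.name}: breakpoint splits feature {f.gene!r}"
                )
    out = PlastomeRecord(
        record.id, new_seq, record.circular, new_feats
    ).sorted_copy()

    event = InversionEvent(
        name=spec.name, left_bp=l, right_bp=r, size=r - l,
        left_label=_igs_label_at(out, l),
        right_label=_igs_label_at(out, r),
        mediating_repeat=(
            (spec.left_anchor[1], len(REPEAT29))
            if spec.left_anchor[0] == "repeat" else None
        ),
    )
    return out, event


def _igs_label_at(record: PlastomeRecord, pos: int) -> str:
    genes = record.gene_features()
    left = max((g for g in genes if g.end <= pos), default=None,
               key=lambda g: g.end)
    right = min((g for g in genes if g.start >= pos), default=None,
                key=lambda g: g.start)
    lname = left.gene if left else "ORIGIN"
    rname = right.gene if right else "ORIGIN"
    return f"IGS({lname}-{rname})"


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

MUTATION_KINDS = (
    "START_CODON_MUTATION", "STOP_CODON_MUTATION", "FRAMESHIFT_INSERTION",
    "FRAMESHIFT_DELETION", "EXON_TRUNCATION", "INTRON_DELETION",
    "WHOLE_GENE_DELETION",
)


@dataclass(frozen=True)
class MutationSpec:
    kind: str
    motif: str = "AAAC"       # FRAMESHIFT_INSERTION payload
    span: int = 0             # deletion length (0 -> kind-specific default)
    keep_fraction: float = 0.2  # EXON_TRUNCATION: exon fraction retained
    exon: int = 0             # 1-based exon targeted by the insertion
    # (0 = last exon; interior occurrences of the motif are preferred so
    # the duplication cannot be mistaken for exon-end length variation)

    def __post_init__(self):
        if self.kind not in MUTATION_KINDS:
            raise ValidationError(f"unknown mutation kind {self.kind!r}")
        if self.kind == "FRAMESHIFT_INSERTION" and len(self.motif) % 3 == 0:
            raise ValidationError(
                "frameshift insertion motif length must not be divisible by 3"
            )
        if self.kind == "FRAMESHIFT_DELETION":
            span = self.span or 2
            if span % 3 == 0:
                raise ValidationError(
                    "frameshift deletion span must not be divisible by 3"
                )


def _delete_span(record: PlastomeRecord, a: int, b: int) -> PlastomeRecord:
    assert 0 <= a < b <= len(record.sequence)
    d = b - a
    new_feats = []
    for f in record.features:
        parts = []
        for s, e in f.parts:
            left = (s, min(e, a))
            right = (max(s, b) - d, e - d)
            for ps, pe in (left, right):
                if pe <= ps:
                    continue
                if parts and parts[-1][1] == ps:  # re-merge a split part
                    parts[-1] = (parts[-1][0], pe)
                else:
                    parts.append((ps, pe))
        if parts:
            new_feats.append(replace(f, parts=tuple(parts)))
    return PlastomeRecord(
        record.id, record.sequence[:a] + record.sequence[b:],
        record.circular, new_feats,
    )


def _insert_at(record: PlastomeRecord, pos: int, ins: str) -> PlastomeRecord:
    d = len(ins)
    new_feats = []
    for f in record.features:
        parts = []
        for s, e in f.parts:
            if e <= pos:
                parts.append((s, e))
            elif s >= pos:
                parts.append((s + d, e + d))
            else:  # insertion inside this part extends it
                parts.append((s, e + d))
        new_feats.append(replace(f, parts=tuple(parts)))
    return PlastomeRecord(
        record.id, record.sequence[:pos] + ins + record.sequence[pos:],
        record.circular, new_feats,
    )


def _substitute(record: PlastomeRecord, pos: int, base: str) -> PlastomeRecord:
    seq = record.sequence
    return PlastomeRecord(
        record.id, seq[:pos] + base + seq[pos + 1:], record.circular,
        list(record.features),
    )


def _coding_to_genomic(f: Feature, c: int) -> int:
    """Genomic index of coding-strand position *c* of CDS feature *f*."""
    acc = 0
    for s, e in f.parts:
        plen = e - s
        if c < acc + plen:
            off = c - acc
            return s + off if f.strand == 1 else e - 1 - off
        acc += plen
    raise ValidationError(f"coding position {c} beyond CDS {f.gene!r}")


def mutate_gene(
    record: PlastomeRecord, gene: str, spec: MutationSpec, seed: int = 0
) -> PlastomeRecord:
    """Apply one mutation to *gene*; annotations are kept consistent.

    Pseudogenizing mutations retain the feature entry; deletions remove the
    locus (features and underlying sequence).
    """
    cds = [f for f in record.features_named(gene, ("CDS",))]
    if not cds:
        raise LookupError_(f"gene {gene!r} absent from record {record.id!r}")
    if len(cds) > 1:
        raise AmbiguityError(
            f"gene {gene!r} has multiple single-copy features"
        )
    f = cds[0]
    rng = np.random.default_rng(seed)
    coding = record.feature_sequence(f)
    kind = spec.kind

    if kind == "START_CODON_MUTATION":
        g = _coding_to_genomic(f, 2)  # ATG -> ATT / complement on minus
        base = "T" if f.strand == 1 else "A"
        return _substitute(record, g, base)

    if kind == "STOP_CODON_MUTATION":
        g = _coding_to_genomic(f, len(coding) - 3)  # TAA -> CAA
        base = "C" if f.strand == 1 else "G"
        return _substitute(record, g, base)

    if kind == "FRAMESHIFT_INSERTION":
        exon_lens = [e - s for s, e in f.parts]
        target = (spec.exon or len(exon_lens)) - 1
        if not 0 <= target < len(exon_lens):
            raise ValidationError(
                f"gene {gene!r} has no exon {spec.exon}"
            )
        lo = sum(exon_lens[:target])
        exon_seq = coding[lo:lo + exon_lens[target]]
        hits = []
        k = exon_seq.find(spec.motif)
        while k >= 0:
            hits.append(k)
            k = exon_seq.find(spec.motif, k + 1)
        if not hits:
            raise ValidationError(
                f"motif {spec.motif!r} not present in exon {target + 1} of "
                f"{gene!r}; cannot duplicate it"
            )
        margin = 12
        interior = [
            h for h in hits
            if h >= margin
            and h + 2 * len(spec.motif) <= exon_lens[target] - margin
        ]
        idx = lo + (interior[0] if interior else hits[0])
        cpos = idx + len(spec.motif)  # duplicate right after the occurrence
        if f.strand == 1:
            gpos = _coding_to_genomic(f, cpos - 1) + 1
            ins = spec.motif
        else:
            gpos = _coding_to_genomic(f, cpos - 1)
            ins = revcomp(spec.motif)
        return _insert_at(record, gpos, ins)

    if kind == "FRAMESHIFT_DELETION":
        span = spec.span or 2
        cpos = len(coding) // 2
        gs = sorted(
            _coding_to_genomic(f, cpos + k) for k in range(span)
        )
        return _delete_span(record, gs[0], gs[-1] + 1)

    if kind == "EXON_TRUNCATION":
        # remove the 3' portion of the last exon, keeping keep_fraction
        s, e = f.parts[-1]
        keep = max(3, int((e - s) * spec.keep_fraction))
        if f.strand == 1:
            return _delete_span(record, s + keep, e)
        return _delete_span(record, s, e - keep)

    if kind == "INTRON_DELETION":
        introns = record.features_named(gene, ("intron",))
        if not introns:
            raise ValidationError(f"gene {gene!r} has no intron")
        s, e = introns[0].parts[0]
        span = spec.span or 200
        span = min(span, (e - s) - 40)
        mid = (s + e) // 2
        return _delete_span(record, mid - span // 2, mid - span // 2 + span)

    if kind == "WHOLE_GENE_DELETION":
        feats = record.features_named(gene, ("CDS", "tRNA", "rRNA", "intron"))
        a = min(x.start for x in feats)
        b = max(x.end for x in feats)
        out = _delete_span(record, a, b)
        out.features = [x for x in out.features if x.gene != gene]
        return out

    raise ValidationError(f"unknown mutation kind {kind!r}")


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelTaxon:
    taxon: str
    tribe: str
    inv36: bool
    inv24: bool
    inv50: bool = True


@dataclass(frozen=True)
class PanelConfig:
    taxa: tuple[PanelTaxon, ...]

    def __post_init__(self):
        names = [t.taxon for t in self.taxa]
        if len(set(names)) != len(names):
            raise ConfigError("panel taxa must be unique")


def _pt(taxon, tribe, i36, i24, i50=True):
    return PanelTaxon(taxon, tribe, i36, i24, i50)


#: 16-taxon screening panel: (taxon, tribe, INV36 state, INV24 state);
#: the three rearrangement-free genera additionally lack INV50.
DEFAULT_PANEL = PanelConfig((
    _pt("Cladrastis wilsonii", "Sophoreae", False, False, False),
    _pt("Styphnolobium japonicum", "Sophoreae", False, False, False),
    _pt("Camoensia brevicalyx", "Sophoreae", False, False, False),
    _pt("Crotalaria capensis", "Crotalarieae", True, False),
    _pt("Lupinus luteus", "Genisteae", True, False),
    _pt("Bolusanthus speciosus", "Sophoreae", True, False),
    _pt("Dicraeopetalum mahafaliense", "Sophoreae", True, False),
    _pt("Anagyris foetida", "Thermopsideae", True, True),
    _pt("Baptisia australis", "Thermopsideae", True, True),
    _pt("Piptanthus nepalensis", "Thermopsideae", True, True),
    _pt("Thermopsis fabacea", "Thermopsideae", True, True),
    _pt("Maackia fauriei", "Sophoreae", True, True),
    _pt("Salweenia bouffordiana", "Sophoreae", True, True),
    _pt("Sophora koreensis", "Sophoreae", True, True),
    _pt("Sophora flavescens", "Sophoreae", True, True),
    _pt("Euchresta japonica", "Euchresteae", True, True),
))


def panel_from_rows(rows) -> PanelConfig:
    """Build a PanelConfig from dict rows with '+'/'-' state symbols."""
    taxa = []
    for row in rows:
        states = {}
        for key in ("INV36", "INV24"):
            sym = row.get(key, "-")
            if sym not in ("+", "-"):
                raise ConfigError(
                    f"taxon {row.get('taxon')!r}: bad state symbol {sym!r} "
                    f"for {key} (expected '+' or '-')"
                )
            states[key] = sym == "+"
        taxa.append(
            PanelTaxon(
                row["taxon"], row.get("tribe", ""), states["INV36"],
                states["INV24"], bool(row.get("INV50", True)),
            )
        )
    return PanelConfig(tuple(taxa))


def build_panel(
    config: PanelConfig,
    seed: int = 0,
    profile: str = "full",
    catalog: GeneCatalog | None = None,
) -> list[tuple[str, PlastomeRecord]]:
    """One synthetic record per panel taxon, with inversions applied."""
    catalog = catalog or default_gene_catalog(profile)
    regions = regions_for_profile(profile)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(config.taxa))
    out = []
    for taxon, child in zip(config.taxa, children):
        rec = generate_plastome(
            catalog, regions, seed=int(child.generate_state(1)[0])
        )
        rec.id = taxon.taxon
        if taxon.inv50:
            rec, _ = apply_inversion(rec, INV50)
        if taxon.inv36:
            rec, _ = apply_inversion(rec, INV36)
        if taxon.inv24:
            rec, _ = apply_inversion(rec, INV24)
        out.append((taxon.taxon, rec))
    return out
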