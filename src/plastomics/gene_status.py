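"""Four-way status classification of a plastid gene against an intact
reference: INTACT / PUTATIVE_PSEUDOGENE / TRUNCATED / DELETED.

The decision procedure, applied in order:

1. locus absent                                          -> DELETED
2. an exon missing, or its aligned coverage of the
   reference exon below the truncation threshold         -> TRUNCATED
3. start codon not ATG/GTG, stop codon lost, net
   frameshifting indels in the exons, or a premature
   in-frame stop                                         -> PUTATIVE_PSEUDOGENE
4. otherwise                                             -> INTACT

Indels touching the terminal bases of an exon are ignored for rule 3
(intact genes tolerate length variation at exon ends); intron damage alone
never pseudogenizes but is recorded as evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguityError, ConfigError
from .io import PlastomeRecord
from .seqs import START_CODONS, STOP_CODONS, translate

# ---------------------------------------------------------------------------
# Locus extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusParts:
    """A gene's exon (and intron) sequences on the coding strand."""

    gene: str
    exons: tuple[str, ...]
    introns: tuple[str, ...]
    strand: int
    coordinates: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.exons:
            raise ConfigError(f"locus {self.gene!r} needs >= 1 exon")

    @property
    def coding(self) -> str:
        return "".join(self.exons)


def extract_locus(record: PlastomeRecord, gene: str) -> LocusParts | None:
    """Exon/intron parts of *gene* in transcription order, coding strand.

    Returns ``None`` when the gene is absent.  Multiple single-copy
    features with the same name raise :class:`AmbiguityError`.
    """
    cds = record.features_named(gene, ("CDS", "tRNA", "rRNA"))
    if not cds:
        return None
    if len(cds) > 1:
        raise AmbiguityError(
            f"gene {gene!r} occurs {len(cds)} times outside the IR; "
            "cannot extract a unique locus"
        )
    f = cds[0]
    exons = tuple(
        _part_seq(record, p, f.strand) for p in f.parts
    )
    introns = tuple(
        _part_seq(record, p, g.strand)
        for g in record.features_named(gene, ("intron",))
        for p in g.parts
    )
    return LocusParts(
        gene=gene, exons=exons, introns=introns, strand=f.strand,
        coordinates=f.parts,
    )


def _part_seq(record: PlastomeRecord, part, strand) -> str:
    s, e = part
    seq = record.sequence[s:e]
    if strand == -1:
        from .seqs import revcomp

        return revcomp(seq)
    return seq


# ---------------------------------------------------------------------------
# Pairwise global alignment (affine gaps, Gotoh)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass(frozen=True)
class Indel:
    ref_pos: int  # 0-based position in the reference
    length: int
    kind: str  # "ins" (extra query bases) or "del" (missing query bases)


@dataclass(frozen=True)
class Alignment:
    aligned_query: str
    aligned_ref: str
    score: float
    indels: tuple[Indel, ...]
    coverage: float  # fraction of reference positions aligned to a base

    @property
    def identity(self) -> float:
        pairs = [
            (a, b)
            for a, b in zip(self.aligned_query, self.aligned_ref)
            if a != "-" and b != "-"
        ]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)


_NEG = -1e30


def global_align(
    query: str, reference: str, scoring: Scoring = Scoring()
) -> Alignment:
    """Optimal global alignment of *query* against *reference*.

    A gap of length k scores ``gap_open + k * gap_extend``.  Traceback is
    deterministic, preferring diagonal, then vertical (query gap-free),
    then horizontal moves on ties.
    """
    if not query or not reference:
        raise ConfigError("global_align requires non-empty sequences")
    n, m = len(query), len(reference)
    o, e = scoring.gap_open, scoring.gap_extend
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(reference.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.float64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.float64)  # gap in query
    F = np.full((n + 1, m + 1), _NEG, dtype=np.float64)  # gap in reference
    M[0, 0] = 0.0
    js = np.arange(1, m + 1, dtype=np.float64)
    E[0, 1:] = o + e * js
    F[1:, 0] = o + e * np.arange(1, n + 1, dtype=np.float64)

    sub = np.where(q[:, None] == r[None, :], scoring.match, scoring.mismatch)
    ek = e * np.arange(m + 1, dtype=np.float64)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        F[i, 1:] = np.maximum(F[i - 1, 1:] + e, prev_best[1:] + o + e)
        # E within the row via prefix max of (max(M,F)[k] + o - e*k)
        mf = np.maximum(M[i], F[i])
        t = mf + o - ek
        run = np.maximum.accumulate(t[:-1])
        E[i, 1:] = run + ek[1:]

    # traceback (recomputes decisions from the stored matrices; ties prefer
    # diagonal, then vertical, then horizontal / gap extension over opening)
    eps = 1e-9
    out_q: list[str] = []
    out_r: list[str] = []
    i, j = n, m
    finals = (M[i, j], F[i, j], E[i, j])
    score = max(finals)
    state = int(np.argmax(finals))
    while i > 0 or j > 0:
        if state == 0:  # diagonal: consumed q[i-1] and r[j-1]
            out_q.append(query[i - 1])
            out_r.append(reference[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for k, v in enumerate((M[i, j], F[i, j], E[i, j])):
                if abs(v - target) < eps:
                    state = k
                    break
        elif state == 1:  # vertical: consumed q[i-1], gap in reference
            out_q.append(query[i - 1])
            out_r.append("-")
            extend = abs(F[i, j] - (F[i - 1, j] + e)) < eps
            i -= 1
            if not extend:
                target = F[i + 1, j] - (o + e)
                state = 0 if abs(M[i, j] - target) < eps else 2
        else:  # horizontal: gap in query, consumed r[j-1]
            out_q.append("-")
            out_r.append(reference[j - 1])
            extend = abs(E[i, j] - (E[i, j - 1] + e)) < eps
            j -= 1
            if not extend:
                target = E[i, j + 1] - (o + e)
                state = 0 if abs(M[i, j] - target) < eps else 1
    aq = "".join(reversed(out_q))
    ar = "".join(reversed(out_r))
    return Alignment(
        aligned_query=aq,
        aligned_ref=ar,
        score=float(score),
        indels=tuple(_collect_indels(aq, ar)),
        coverage=_coverage(aq, ar, m),
    )


def _collect_indels(aq: str, ar: str):
    indels = []
    ref_pos = 0
    k = 0
    while k < len(aq):
        if ar[k] == "-":  # insertion relative to reference
            length = 0
            while k < len(aq) and ar[k] == "-":
                length += 1
                k += 1
            indels.append(Indel(ref_pos, length, "ins"))
        elif aq[k] == "-":
            length = 0
            start = ref_pos
            while k < len(aq) and k < len(ar) and aq[k] == "-" and ar[k] != "-":
                length += 1
                ref_pos += 1
                k += 1
            indels.append(Indel(start, length, "del"))
        else:
            ref_pos += 1
            k += 1
    return indels


def _coverage(aq: str, ar: str, ref_len: int) -> float:
    aligned = sum(1 for a, b in zip(aq, ar) if a != "-" and b != "-")
    return aligned / ref_len if ref_len else 0.0


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

CATEGORIES = ("INTACT", "PUTATIVE_PSEUDOGENE", "TRUNCATED", "DELETED")


@dataclass(frozen=True)
class Thresholds:
    truncation_coverage: float = 0.5
    end_window: int = 9        # exon-terminal bp where indels are ignored
    stop_tail_fraction: float = 0.05  # in-frame stops this close to the
    # end of the coding sequence are treated as the terminator

    def __post_init__(self):
        if not 0 < self.truncation_coverage < 1:
            raise ConfigError("truncation_coverage must lie in (0, 1)")
        if not 0 < self.stop_tail_fraction < 1:
            raise ConfigError("stop_tail_fraction must lie in (0, 1)")


@dataclass
class GeneStatusReport:
    gene: str
    category: str
    evidence: list[str] = field(default_factory=list)
    exon_coverages: tuple[float, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigError(f"unknown category {self.category!r}")
        if self.category != "INTACT" and not self.evidence:
            raise ConfigError(
                f"{self.category} report for {self.gene!r} lacks evidence"
            )


def classify_locus(
    query: LocusParts | None,
    reference: LocusParts,
    thresholds: Thresholds = Thresholds(),
    scoring: Scoring = Scoring(),
) -> GeneStatusReport:
    """Classify *query* against a verified-intact *reference* locus."""
    gene = reference.gene
    if query is None:
        return GeneStatusReport(gene, "DELETED", ["locus absent"])

    evidence: list[str] = []

    # --- rule 2: truncation ------------------------------------------------
    coverages = []
    exon_alignments: list[Alignment | None] = []
    truncated = False
    for k, ref_exon in enumerate(reference.exons):
        if k >= len(query.exons) or not query.exons[k]:
            coverages.append(0.0)
            exon_alignments.append(None)
            evidence.append(f"exon{k + 1} missing")
            truncated = True
            continue
        aln = global_align(query.exons[k], ref_exon, scoring)
        coverages.append(aln.coverage)
        exon_alignments.append(aln)
        if aln.coverage < thresholds.truncation_coverage:
            evidence.append(
                f"exon{k + 1} coverage {aln.coverage:.2f} < "
                f"{thresholds.truncation_coverage}"
            )
            truncated = True
    if truncated:
        return GeneStatusReport(
            gene, "TRUNCATED", evidence, tuple(coverages)
        )

    # --- rule 3: pseudogene ------------------------------------------------
    pseudo = False
    coding = query.coding
    start = coding[:3]
    if start not in START_CODONS:
        evidence.append(f"start codon {start} (expected ATG/GTG)")
        pseudo = True
    if coding[-3:] not in STOP_CODONS:
        evidence.append(f"stop codon lost (terminal codon {coding[-3:]})")
        pseudo = True

    net_indel = 0
    w = thresholds.end_window
    for k, aln in enumerate(exon_alignments):
        if aln is None:
            continue
        ref_len = len(reference.exons[k])
        for ind in aln.indels:
            internal = w <= ind.ref_pos <= ref_len - w
            if not internal:
                continue
            net_indel += ind.length if ind.kind == "ins" else -ind.length
            evidence.append(
                f"exon{k + 1} internal {ind.kind} of {ind.length} bp at "
                f"reference position {ind.ref_pos}"
            )
    if net_indel % 3 != 0:
        evidence.append(
            f"net internal coding indel of {net_indel:+d} bp shifts frame"
        )
        pseudo = True

    protein = translate(coding)
    tail = max(1, int(round(len(protein) * thresholds.stop_tail_fraction)))
    premature = [
        i for i, aa in enumerate(protein[:-1]) if aa == "*"
        if i < len(protein) - 1 - tail
    ]
    if premature:
        evidence.append(
            f"internal stop codon(s) at amino-acid position(s) "
            f"{premature[:5]} of {len(protein)}"
        )
        pseudo = True

    # intron evidence only (never pseudogenizes on its own)
    for k, ref_intron in enumerate(reference.introns):
        if k >= len(query.introns):
            evidence.append(f"intron{k + 1} missing")
            continue
        if len(query.introns[k]) < len(ref_intron) - 30:
            evidence.append(
                f"intron{k + 1} shortened by "
                f"{len(ref_intron) - len(query.introns[k])} bp"
            )

    if pseudo:
        return GeneStatusReport(
            gene, "PUTATIVE_PSEUDOGENE", evidence, tuple(coverages)
        )
    return GeneStatusReport(gene, "INTACT", evidence, tuple(coverages))


def survey_gene(
    records: list[tuple[str, PlastomeRecord]],
    gene: str,
    reference: LocusParts,
    thresholds: Thresholds = Thresholds(),
) -> tuple[dict[str, GeneStatusReport], Counter]:
    """Classify *gene* across a panel; returns per-taxon reports + tallies."""
    reports = {}
    for taxon, record in records:
        query = extract_locus(record, gene)
        reports[taxon] = classify_locus(query, reference, thresholds)
    tally = Counter(r.category for r in reports.values())
    for cat in CATEGORIES:
        tally.setdefault(cat, 0)
    return reports, tally
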