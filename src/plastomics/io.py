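"""Reading and writing of annotated circular plastome records.

Internal convention: 0-based half-open coordinates everywhere; conversion to
GenBank's 1-based inclusive intervals happens only at (de)serialization.
A feature on a circular record that spans the origin is stored as ordered
parts, each lying inside ``[0, length)``; in GenBank it round-trips through
``join()`` location syntax.

Supported formats:

* ``genbank`` -- a minimal GenBank flat-file dialect (LOCUS/FEATURES/ORIGIN
  with gene, CDS, tRNA, rRNA, intron and misc_feature keys), via Biopython.
* ``fasta+table`` -- a FASTA file plus a sibling TSV feature table
  (``<stem>.features.tsv``).

Trees are Newick, via dendropy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .seqs import check_alphabet, revcomp

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "intron", "IGS_label")

#: Feature kinds that denote an actual gene locus (as opposed to a label).
GENE_KINDS = ("CDS", "tRNA", "rRNA")

_GB_KEY_FOR_KIND = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "intron": "intron",
    "IGS_label": "misc_feature",
}
_KIND_FOR_GB_KEY = {v: k for k, v in _GB_KEY_FOR_KIND.items()}


@dataclass(frozen=True)
class Feature:
    """One annotated element: a gene part set on a strand.

    ``parts`` are ``(start, end)`` half-open intervals in *transcription
    order* (for minus-strand features the genomically-last exon comes
    first).  A feature wrapping the circular origin is split into parts.
    """

    gene: str
    kind: str
    strand: int
    parts: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise ValidationError(f"strand must be +1/-1, got {self.strand}")
        if not self.parts:
            raise ValidationError(f"feature {self.gene!r} has no parts")
        for s, e in self.parts:
            if s < 0 or e <= s:
                raise ValidationError(
                    f"feature {self.gene!r} has invalid part ({s}, {e})"
                )

    @property
    def start(self) -> int:
        """Genomically smallest coordinate over all parts."""
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        """Genomically largest coordinate over all parts."""
        return max(e for _, e in self.parts)

    @property
    def span(self) -> int:
        return sum(e - s for s, e in self.parts)

    def shifted(self, delta: int) -> "Feature":
        return replace(
            self, parts=tuple((s + delta, e + delta) for s, e in self.parts)
        )


@dataclass
class PlastomeRecord:
    """A circular (or linear) annotated genome."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        check_alphabet(self.sequence, context=f"record {self.id!r}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if e > n:
                    raise ValidationError(
                        f"record {self.id!r}: feature {f.gene!r} part "
                        f"({s}, {e}) outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    # -- feature access -------------------------------------------------

    def features_named(self, gene: str, kinds=GENE_KINDS) -> list[Feature]:
        return [f for f in self.features if f.gene == gene and f.kind in kinds]

    def gene_features(self) -> list[Feature]:
        """All gene-locus features, sorted by genomic start."""
        feats = [f for f in self.features if f.kind in GENE_KINDS]
        return sorted(feats, key=lambda f: f.start)

    def feature_sequence(self, f: Feature) -> str:
        """Concatenated part sequences on the coding strand."""
        chunks = [self.sequence[s:e] for s, e in f.parts]
        if f.strand == -1:
            return "".join(revcomp(c) for c in chunks)
        return "".join(chunks)

    def sorted_copy(self) -> "PlastomeRecord":
        feats = sorted(self.features, key=lambda f: (f.start, f.gene, f.kind))
        return PlastomeRecord(self.id, self.sequence, self.circular, feats)

    def equal_content(self, other: "PlastomeRecord") -> bool:
        """Same sequence, topology and feature set (order-insensitive)."""
        return (
            self.sequence == other.sequence
            and self.circular == other.circular
            and sorted(self.features, key=lambda f: (f.start, f.gene, f.kind))
            == sorted(other.features, key=lambda f: (f.start, f.gene, f.kind))
        )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------


def _feature_to_biopython(f: Feature) -> SeqFeature:
    locs = [SimpleLocation(s, e, strand=f.strand) for s, e in f.parts]
    if f.strand == -1:
        # GenBank lists complement(join(...)) parts in genomic order while
        # we store transcription order; reverse so round-trips are stable.
        locs = locs[::-1]
    loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
    return SeqFeature(
        loc, type=_GB_KEY_FOR_KIND[f.kind], qualifiers={"gene": [f.gene]}
    )


def _feature_from_biopython(sf: SeqFeature, record_id: str) -> Feature | None:
    kind = _KIND_FOR_GB_KEY.get(sf.type)
    if kind is None:
        return None  # unknown key: preserved on read path only via warning
    quals = sf.qualifiers
    name = (quals.get("gene") or quals.get("label") or ["?"])[0]
    strand = sf.location.strand or 1
    parts = [(int(p.start), int(p.end)) for p in sf.location.parts]
    if strand == -1:
        parts = parts[::-1]
    return Feature(gene=name, kind=kind, strand=strand, parts=tuple(parts))


def _record_to_biopython(record: PlastomeRecord) -> SeqRecord:
    sr = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16].replace(" ", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    sr.features = [_feature_to_biopython(f) for f in record.features]
    return sr


def load_plastome(
    path: str | os.PathLike,
    format: str = "genbank",
    *,
    circular: bool | None = None,
) -> PlastomeRecord:
    """Load a plastome from *path*.

    ``format`` is ``"genbank"`` or ``"fasta+table"``.  Features are returned
    sorted by ascending genomic start.  The circular flag is read from the
    record header when present; *circular* overrides/defaults it.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    if format == "genbank":
        record = _load_genbank(path)
    elif format == "fasta+table":
        record = _load_fasta_table(path)
    else:
        raise ParseError(f"unknown format {format!r}")
    if circular is not None:
        record.circular = circular
    record.validate()
    return record.sorted_copy()


def _load_genbank(path: str) -> PlastomeRecord:
    try:
        sr = SeqIO.read(path, "genbank")
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ParseError(f"malformed GenBank file {path}: {exc}") from exc
    seq = str(sr.seq).upper()
    feats = []
    for sf in sr.features:
        f = _feature_from_biopython(sf, sr.id)
        if f is not None:
            feats.append(f)
    topology = sr.annotations.get("topology", "circular")
    return PlastomeRecord(
        id=sr.id, sequence=seq, circular=topology == "circular", features=feats
    )


def _table_path(fasta_path: str) -> str:
    stem, _ = os.path.splitext(fasta_path)
    return stem + ".features.tsv"


def _load_fasta_table(path: str) -> PlastomeRecord:
    try:
        sr = SeqIO.read(path, "fasta")
    except Exception as exc:
        raise ParseError(f"malformed FASTA file {path}: {exc}") from exc
    circular = "circular=false" not in sr.description
    feats: list[Feature] = []
    tpath = _table_path(path)
    if os.path.exists(tpath):
        with open(tpath) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if cols[0] == "gene":  # header
                    continue
                if len(cols) != 4:
                    raise ParseError(
                        f"{tpath}:{lineno}: expected 4 tab-separated "
                        f"columns, got {len(cols)}"
                    )
                gene, kind, strand_s, parts_s = cols
                try:
                    strand = {"+": 1, "-": -1}[strand_s]
                    parts = tuple(
                        (int(a), int(b))
                        for a, b in (p.split("-") for p in parts_s.split(";"))
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"{tpath}:{lineno}: {exc}") from exc
                feats.append(Feature(gene, kind, strand, parts))
    return PlastomeRecord(
        id=sr.id, sequence=str(sr.seq).upper(), circular=circular,
        features=feats,
    )


def save_plastome(
    record: PlastomeRecord, path: str | os.PathLike, format: str = "genbank"
) -> None:
    """Write *record* so that re-loading yields equal content."""
    path = os.fspath(path)
    record.validate()
    if format == "genbank":
        SeqIO.write(_record_to_biopython(record), path, "genbank")
    elif format == "fasta+table":
        sr = SeqRecord(
            Seq(record.sequence),
            id=record.id,
            description=f"circular={'true' if record.circular else 'false'}",
        )
        SeqIO.write(sr, path, "fasta")
        with open(_table_path(path), "w") as fh:
            fh.write("gene\tkind\tstrand\tparts\n")
            for f in record.features:
                parts_s = ";".join(f"{s}-{e}" for s, e in f.parts)
                strand_s = "+" if f.strand == 1 else "-"
                fh.write(f"{f.gene}\t{f.kind}\t{strand_s}\t{parts_s}\n")
    else:
        raise ParseError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def load_tree(path_or_string: str | os.PathLike) -> dendropy.Tree:
    """Load a rooted Newick tree; leaf labels must be unique."""
    if isinstance(path_or_string, str) and path_or_string.strip().startswith(
        "("
    ):
        src = {"data": path_or_string}
    else:
        p = os.fspath(path_or_string)
        if not os.path.exists(p):
            raise ParseError(f"no such file: {p}")
        src = {"path": p}
    try:
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **src
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        raise ParseError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValidationError(f"duplicate leaf labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


def tree_leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]
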