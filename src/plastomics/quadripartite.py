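"""Inverted-repeat detection and LSC/IRa/SSC/IRb partitioning.

Detection is exact-match reverse-complement search on the circular
sequence, by binary search over candidate lengths with a rolling hash and
direct string verification.  The two single-copy stretches between the
repeat copies become LSC (longer) and SSC (shorter); IRa is the repeat copy
downstream of the LSC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PartitionError, ValidationError
from .io import PlastomeRecord
from .seqs import gc_percent, revcomp

_ENC = np.zeros(256, dtype=np.uint64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i + 1


@dataclass(frozen=True)
class RepeatPair:
    """Two disjoint circular intervals; copy A equals revcomp(copy B)."""

    start_a: int
    start_b: int
    length: int
    degenerate: bool = False

    def intervals(self, n: int) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.start_a, self.start_a + self.length),
            (self.start_b, self.start_b + self.length),
        )


@dataclass(frozen=True)
class QuadripartitePartition:
    """Circular intervals (end may exceed n, meaning wrap) tiling the genome."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    total: int

    def __post_init__(self):
        if self.lsc_len + self.ssc_len + 2 * self.ir_len != self.total:
            raise ValidationError(
                "quadripartite intervals do not tile the circle"
            )
        if self.lsc_len < self.ssc_len:
            raise ValidationError("LSC shorter than SSC")

    @staticmethod
    def _length(iv: tuple[int, int]) -> int:
        return iv[1] - iv[0]

    @property
    def lsc_len(self) -> int:
        return self._length(self.lsc)

    @property
    def ssc_len(self) -> int:
        return self._length(self.ssc)

    @property
    def ir_len(self) -> int:
        return self._length(self.ira)


_HASH_BASE = 1099511628211  # odd, hence invertible modulo 2**64
_HASH_BASE_INV = pow(_HASH_BASE, -1, 2**64)


def _window_hashes(codes: np.ndarray, L: int) -> np.ndarray:
    """Comparable hashes of all length-L windows, O(n) (uint64 wraparound).

    ``H[i] = (S[i+L] - S[i]) * B**-i`` with ``S`` the prefix sum of
    ``codes[t] * B**t``; equal windows hash equal.  All arithmetic is
    modulo 2**64 via uint64 overflow.
    """
    n = len(codes)
    with np.errstate(over="ignore"):
        pow_b = np.ones(n, dtype=np.uint64)
        pow_b[1:] = _HASH_BASE
        pow_b = np.multiply.accumulate(pow_b)
        inv_b = np.ones(n - L + 1, dtype=np.uint64)
        inv_b[1:] = _HASH_BASE_INV
        inv_b = np.multiply.accumulate(inv_b)
        prefix = np.zeros(n + 1, dtype=np.uint64)
        np.cumsum(codes * pow_b, out=prefix[1:])
        return (prefix[L:] - prefix[:-L]) * inv_b


def _circ_disjoint(i: int, j: int, L: int, n: int) -> bool:
    """Intervals [i,i+L) and [j,j+L) disjoint on the circle of size n."""
    if i == j:
        return False
    gap1 = (j - (i + L)) % n
    gap2 = (i - (j + L)) % n
    return gap1 + gap2 == n - 2 * L and gap1 >= 0 and gap2 >= 0 and 2 * L <= n


def _rc_matches(
    seq: str, L: int, first_only: bool = False
) -> list[tuple[int, int]]:
    """Circular positions (i, j), i <= j, of disjoint intervals with
    ``seq[i:i+L] == revcomp(seq[j:j+L])``, verified by direct comparison.

    With ``first_only`` returns at most one verified pair (existence test).
    """
    n = len(seq)
    if L > n // 2:
        return []
    ext = seq + seq[: L - 1]
    rc = revcomp(seq)
    rc_ext = rc + rc[: L - 1]
    codes = _ENC[np.frombuffer(ext.encode(), dtype=np.uint8)]
    rc_codes = _ENC[np.frombuffer(rc_ext.encode(), dtype=np.uint8)]
    h_fwd = _window_hashes(codes, L)[:n]
    h_rc = _window_hashes(rc_codes, L)[:n]

    common = np.intersect1d(h_fwd, h_rc)
    if common.size == 0:
        return []
    ext2 = seq + seq  # for verification slices
    out = []
    for h in common:
        fwd_pos = np.flatnonzero(h_fwd == h)
        rc_pos = np.flatnonzero(h_rc == h)
        for jr in rc_pos.tolist():
            j = (n - jr - L) % n  # forward-strand start of the rc window
            for i in fwd_pos.tolist():
                a, b = (i, j) if i <= j else (j, i)
                if not _circ_disjoint(a, b, L, n):
                    continue
                if ext2[a : a + L] == revcomp(ext2[b : b + L]):
                    out.append((a, b))
                    if first_only:
                        return out
    return sorted(set(out))


def find_inverted_repeat(
    sequence: str, min_len: int = 1000
) -> RepeatPair | None:
    """Longest pair of disjoint intervals A, B with A == revcomp(B).

    Exact matching; returns ``None`` when no such pair of length >= min_len
    exists (including when the sequence is shorter than ``2 * min_len``).
    The result is maximal: extending either copy by one base on either end
    breaks the equality.  Ties prefer the pair whose copies are farthest
    apart on the circle, then the lowest start coordinate.
    """
    if min_len < 100:
        raise ValidationError("min_len must be >= 100")
    n = len(sequence)
    if n < 2 * min_len:
        return None
    if not _rc_matches(sequence, min_len, first_only=True):
        return None
    lo, hi = min_len, n // 2  # invariant: match exists at lo, none above hi
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _rc_matches(sequence, mid, first_only=True):
            lo = mid
        else:
            hi = mid - 1
    L = lo
    pairs = _rc_matches(sequence, L)

    def tie_key(p):
        i, j = p
        gap1 = (j - (i + L)) % n
        gap2 = (i - (j + L)) % n
        return (-min(gap1, gap2), i, j)

    i, j = min(pairs, key=tie_key)
    return RepeatPair(i, j, L, degenerate=2 * L >= n)


def partition_genome(
    record: PlastomeRecord, min_ir_len: int = 1000
) -> QuadripartitePartition:
    """Partition a circular record into LSC / IRa / SSC / IRb.

    Region lengths are invariant under rotation of the input; IRa is the
    repeat copy immediately downstream of the LSC.
    """
    pair = find_inverted_repeat(record.sequence, min_ir_len)
    if pair is None:
        raise PartitionError(
            f"no inverted repeat of length >= {min_ir_len} found; "
            "try lowering --min-ir-len"
        )
    n = len(record.sequence)
    a, b, L = pair.start_a, pair.start_b, pair.length
    gap_ab = (b - (a + L)) % n  # single-copy stretch following copy A
    gap_ba = (a - (b + L)) % n  # single-copy stretch following copy B
    if gap_ab >= gap_ba:
        lsc = (a + L, a + L + gap_ab)
        ira = (b, b + L)
        ssc = (b + L, b + L + gap_ba)
        irb = (a, a + L)
    else:
        lsc = (b + L, b + L + gap_ba)
        ira = (a, a + L)
        ssc = (a + L, a + L + gap_ab)
        irb = (b, b + L)
    # normalize: express each interval with start in [0, n)
    def norm(iv):
        s, e = iv
        return (s % n, s % n + (e - s))

    return QuadripartitePartition(
        lsc=norm(lsc), ira=norm(ira), ssc=norm(ssc), irb=norm(irb), total=n
    )


@dataclass(frozen=True)
class SummaryStats:
    total_bp: int
    lsc_len: int
    ssc_len: int
    ir_len: int
    gc_pct: float
    at_pct: float
    coding_cds_pct: float
    coding_cds_rna_pct: float
    n_unique_rrna: int
    n_unique_trna: int
    n_unique_cds: int
    n_features_unique: int
    n_features_with_ir_duplicates: int

    def __post_init__(self):
        if not 0 <= self.coding_cds_pct <= 100:
            raise ValidationError("coding fraction outside [0, 100]")


def _union_bp(parts: list[tuple[int, int]], n: int) -> int:
    """Total bp covered by the union of (possibly wrapping) intervals."""
    events = []
    for s, e in parts:
        s %= n
        e2 = s + (e - s)
        if e2 <= n:
            events.append((s, e2))
        else:
            events.append((s, n))
            events.append((0, e2 - n))
    events.sort()
    covered = 0
    cur_s, cur_e = None, None
    for s, e in events:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def genome_summary(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> SummaryStats:
    """Composition and content statistics over the whole circle.

    The coding fraction counts IR-duplicated genes in both copies (it is a
    fraction of total sequence); unique counts deduplicate by gene name.
    Two coding variants are reported: CDS exons only, and CDS plus
    structural RNAs.
    """
    n = len(record.sequence)
    gc = gc_percent(record.sequence)
    cds_parts = [
        p for f in record.features if f.kind == "CDS" for p in f.parts
    ]
    rna_parts = [
        p
        for f in record.features
        if f.kind in ("tRNA", "rRNA")
        for p in f.parts
    ]
    uniq = {
        kind: {f.gene for f in record.features if f.kind == kind}
        for kind in ("CDS", "tRNA", "rRNA")
    }
    n_total = sum(
        1 for f in record.features if f.kind in ("CDS", "tRNA", "rRNA")
    )
    n_unique = sum(len(v) for v in uniq.values())
    return SummaryStats(
        total_bp=n,
        lsc_len=partition.lsc_len,
        ssc_len=partition.ssc_len,
        ir_len=partition.ir_len,
        gc_pct=gc,
        at_pct=100.0 - gc,
        coding_cds_pct=100.0 * _union_bp(cds_parts, n) / n,
        coding_cds_rna_pct=100.0 * _union_bp(cds_parts + rna_parts, n) / n,
        n_unique_rrna=len(uniq["rRNA"]),
        n_unique_trna=len(uniq["tRNA"]),
        n_unique_cds=len(uniq["CDS"]),
        n_features_unique=n_unique,
        n_features_with_ir_duplicates=n_total,
    )
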