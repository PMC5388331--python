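"""Inversion detection via signed gene-order permutations.

Genomes are linearized by cutting the circle at the IRb/LSC junction and
reading LSC, IRa, SSC (one IR copy is removed before comparison).  Gene
orders become signed permutations relative to a reference; collinear blocks
are the maximal runs between non-conserved adjacencies; inversion histories
are reconstructed greedily and validated against an exact breadth-first
reversal-distance oracle on small marker counts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .errors import MarkerSetError, ValidationError
from .events import InversionEvent
from .io import PlastomeRecord
from .quadripartite import QuadripartitePartition, partition_genome


# ---------------------------------------------------------------------------
# Linearization and signed permutations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedPermutation:
    taxon: str
    order: tuple[int, ...]  # signed 1-based marker ids
    markers: tuple[str, ...]  # marker names, index k <-> id k+1

    def __post_init__(self):
        ids = sorted(abs(x) for x in self.order)
        if ids != list(range(1, len(self.markers) + 1)):
            raise ValidationError(
                f"{self.taxon}: order is not a signed permutation of "
                f"1..{len(self.markers)}"
            )

    @property
    def n(self) -> int:
        return len(self.order)

    def is_identity(self) -> bool:
        return self.order == tuple(range(1, self.n + 1))


def linear_gene_order(
    record: PlastomeRecord,
    partition: QuadripartitePartition | None = None,
    min_ir_len: int = 1000,
) -> list[tuple[str, int, int, int]]:
    """Genes in LSC + IRa + SSC order (IRb dropped).

    Returns ``(gene, strand, start, end)`` tuples with coordinates in the
    rotated frame starting at the LSC origin.
    """
    part = partition or partition_genome(record, min_ir_len)
    n = part.total
    offset = part.lsc[0]
    keep_until = part.ssc[1] - part.lsc[0]  # rotated end of SSC
    out = []
    for f in record.gene_features():
        mid = (f.start + f.end) // 2
        rot = (mid - offset) % n
        if rot >= keep_until:  # inside IRb
            continue
        start = (f.start - offset) % n
        out.append((f.gene, f.strand, start, start + (f.end - f.start)))
    out.sort(key=lambda t: t[2])
    return out


def shared_gene_order(
    record: PlastomeRecord,
    reference: PlastomeRecord,
    marker_set: tuple[str, ...] | None = None,
    min_ir_len: int = 1000,
) -> SignedPermutation:
    """Signed permutation of *record*'s marker order relative to *reference*.

    Every marker must occur exactly once in each genome's single-copy
    representation; the reference maps to the identity.
    """
    ref_order = linear_gene_order(reference, min_ir_len=min_ir_len)
    rec_order = linear_gene_order(record, min_ir_len=min_ir_len)
    if marker_set is None:
        marker_set = tuple(g for g, *_ in ref_order)

    def pick(order, label):
        seen: dict[str, tuple[int, int]] = {}
        dup, missing = [], []
        wanted = set(marker_set)
        for g, strand, s, e in order:
            if g not in wanted:
                continue
            if g in seen:
                dup.append(g)
            seen[g] = (strand, s)
        missing = [g for g in marker_set if g not in seen]
        if dup or missing:
            raise MarkerSetError(
                f"{label}: duplicated markers {sorted(set(dup))}, "
                f"missing markers {missing}"
            )
        return seen

    ref_map = pick(ref_order, reference.id)
    rec_map = pick(rec_order, record.id)

    ref_rank = {
        g: k + 1
        for k, (g, *_rest) in enumerate(
            sorted(
                ((g, *ref_map[g]) for g in marker_set),
                key=lambda t: t[2],
            )
        )
    }
    markers = tuple(sorted(marker_set, key=lambda g: ref_rank[g]))
    signed = []
    for g, strand, s, e in sorted(
        ((g, *rec_map[g], 0) for g in marker_set), key=lambda t: t[2]
    ):
        rel = strand * ref_map[g][0]
        signed.append(rel * ref_rank[g])
    return SignedPermutation(record.id, tuple(signed), markers)


# ---------------------------------------------------------------------------
# Collinear blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollinearBlock:
    block_id: int
    marker_ids: tuple[int, ...]  # reference ids, ascending
    intervals: dict  # taxon -> (start_index, end_index) in that permutation
    orientations: dict  # taxon -> +1 / -1

    def __hash__(self):  # intervals/orientations excluded
        return hash((self.block_id, self.marker_ids))


def _adjacencies(order: tuple[int, ...]) -> set[tuple[int, int]]:
    """Signed adjacencies, normalized so (a, b) == (-b, -a)."""
    out = set()
    for a, b in zip(order, order[1:]):
        out.add((a, b) if (a, b) <= (-b, -a) else (-b, -a))
    return out


def lcb_decomposition(
    perms: list[SignedPermutation],
) -> list[CollinearBlock]:
    """Maximal runs between adjacencies not conserved across all inputs.

    Blocks tile every permutation; merging two adjacent blocks would break
    conservation in at least one genome.
    """
    if len(perms) < 2:
        raise ValidationError("need >= 2 permutations")
    base = perms[0]
    for p in perms[1:]:
        if p.markers != base.markers:
            raise MarkerSetError(
                f"{p.taxon}: marker set differs from {base.taxon}"
            )
    conserved = set.intersection(*(_adjacencies(p.order) for p in perms))

    n = base.n
    # cut the identity (reference frame) wherever (+k, +k+1) not conserved
    blocks: list[list[int]] = [[1]]
    for k in range(1, n):
        adj = (k, k + 1)
        norm = adj if adj <= (-adj[1], -adj[0]) else (-adj[1], -adj[0])
        if norm in conserved:
            blocks[-1].append(k + 1)
        else:
            blocks.append([k + 1])

    out = []
    for bid, ids in enumerate(blocks, 1):
        intervals, orientations = {}, {}
        idset = set(ids)
        for p in perms:
            pos = [k for k, v in enumerate(p.order) if abs(v) in idset]
            if pos != list(range(pos[0], pos[0] + len(ids))):
                raise ValidationError(
                    f"block {bid} not contiguous in {p.taxon}: non-inversion "
                    "rearrangement present"
                )
            seg = p.order[pos[0] : pos[0] + len(ids)]
            if list(seg) == sorted(idset):
                orientations[p.taxon] = 1
            elif [-x for x in seg[::-1]] == sorted(idset):
                orientations[p.taxon] = -1
            else:
                raise ValidationError(
                    f"block {bid} internally rearranged in {p.taxon}"
                )
            intervals[p.taxon] = (pos[0], pos[0] + len(ids))
        out.append(
            CollinearBlock(bid, tuple(sorted(idset)), intervals, orientations)
        )
    return out


# ---------------------------------------------------------------------------
# Reversal distance (exact, small n)
# ---------------------------------------------------------------------------


def _all_reversals(order: tuple[int, ...]):
    n = len(order)
    for i in range(n):
        for j in range(i + 1, n + 1):
            yield (
                order[:i]
                + tuple(-x for x in reversed(order[i:j]))
                + order[j:]
            )


def reversal_distance_bfs(
    perm: SignedPermutation | tuple[int, ...], max_markers: int = 10
) -> int:
    """Exact minimum signed reversals to identity, by breadth-first search."""
    order = perm.order if isinstance(perm, SignedPermutation) else tuple(perm)
    n = len(order)
    if n > max_markers:
        raise ValidationError(
            f"{n} markers exceeds BFS limit of {max_markers}"
        )
    identity = tuple(range(1, n + 1))
    if order == identity:
        return 0
    seen = {order}
    frontier = deque([(order, 0)])
    while frontier:
        cur, d = frontier.popleft()
        for nxt in _all_reversals(cur):
            if nxt == identity:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    raise AssertionError("unreachable: reversal graph is connected")


def _bfs_sorting_path(order: tuple[int, ...]) -> list[tuple[int, int]]:
    """A minimum-length sequence of reversal intervals sorting *order*."""
    identity = tuple(range(1, len(order) + 1))
    if order == identity:
        return []
    parents: dict[tuple, tuple] = {order: None}
    frontier = deque([order])
    while frontier:
        cur = frontier.popleft()
        n = len(cur)
        for i in range(n):
            for j in range(i + 1, n + 1):
                nxt = (
                    cur[:i]
                    + tuple(-x for x in reversed(cur[i:j]))
                    + cur[j:]
                )
                if nxt in parents:
                    continue
                parents[nxt] = (cur, (i, j))
                if nxt == identity:
                    path = []
                    node = nxt
                    while parents[node] is not None:
                        prev, iv = parents[node]
                        path.append(iv)
                        node = prev
                    return path[::-1]
                frontier.append(nxt)
    raise AssertionError("unreachable: reversal graph is connected")


# ---------------------------------------------------------------------------
# Inversion-history inference
# ---------------------------------------------------------------------------


def _correct_adjacencies(order: tuple[int, ...]) -> int:
    n = len(order)
    ext = (0,) + order + (n + 1,)
    return sum(1 for a, b in zip(ext, ext[1:]) if b == a + 1)


def infer_inversion_events(
    perm: SignedPermutation,
    record: PlastomeRecord | None = None,
    bfs_limit: int = 10,
) -> list[InversionEvent]:
    """Greedy nested-inversion reconstruction of *perm*'s history.

    Repeatedly reverses the interval that most increases the number of
    correctly signed, correctly ordered adjacencies (ties: longest, then
    leftmost), until the identity is reached.  Events are reported
    outermost-first.  For small permutations the event count is checked
    against the BFS oracle and flagged ``NON_MINIMAL`` when it exceeds it;
    a permutation with no improving reversal is flagged ``UNRESOLVED``.
    """
    order = perm.order
    undo_steps: list[tuple[int, int]] = []  # intervals in current frames
    flags: list[str] = []
    cur = order
    while cur != tuple(range(1, len(cur) + 1)):
        best = None
        cur_score = _correct_adjacencies(cur)
        n = len(cur)
        for i in range(n):
            for j in range(i + 1, n + 1):
                cand = (
                    cur[:i]
                    + tuple(-x for x in reversed(cur[i:j]))
                    + cur[j:]
                )
                gain = _correct_adjacencies(cand) - cur_score
                if gain <= 0:
                    continue
                key = (gain, j - i, -i)  # gain, then longest, then leftmost
                if best is None or key > best[0]:
                    best = (key, (i, j), cand)
        if best is None:
            # No reversal strictly improves the adjacency count: either a
            # non-inversion rearrangement or a greedy dead end.  Complete
            # exactly via BFS when small enough; the flag is kept either way.
            flags.append("UNRESOLVED")
            if len(cur) <= bfs_limit:
                for i, j in _bfs_sorting_path(cur):
                    undo_steps.append((i, j))
                    cur = (
                        cur[:i]
                        + tuple(-x for x in reversed(cur[i:j]))
                        + cur[j:]
                    )
            break
        undo_steps.append(best[1])
        cur = best[2]

    sorted_ok = cur == tuple(range(1, len(cur) + 1))
    if perm.n <= bfs_limit and sorted_ok:
        d = reversal_distance_bfs(perm, bfs_limit)
        if len(undo_steps) > d:
            # replace the greedy reconstruction by an exact minimum one
            flags.append("EXACT_FALLBACK")
            undo_steps = _bfs_sorting_path(order)
    elif sorted_ok is False and "UNRESOLVED" not in flags:
        flags.append("UNRESOLVED")

    # Replay the undo intervals forward to express each event's marker set
    # in the observed permutation, outermost-first = reverse undo order.
    events: list[InversionEvent] = []
    frames = [order]
    cur2 = order
    for i, j in undo_steps:
        cur2 = (
            cur2[:i] + tuple(-x for x in reversed(cur2[i:j])) + cur2[j:]
        )
        frames.append(cur2)
    for step_idx in reversed(range(len(undo_steps))):
        i, j = undo_steps[step_idx]
        frame = frames[step_idx]
        marker_ids = [abs(x) for x in frame[i:j]]
        names = tuple(perm.markers[k - 1] for k in sorted(marker_ids))
        left_bp, right_bp, size = 0, 0, 0
        left_label = right_label = ""
        repeat = None
        if record is not None:
            left_bp, right_bp, left_label, right_label, repeat = (
                _locate_in_record(record, perm, marker_ids)
            )
            size = right_bp - left_bp
        events.append(
            InversionEvent(
                name=f"event{len(undo_steps) - step_idx}",
                left_bp=left_bp,
                right_bp=right_bp,
                size=size,
                left_label=left_label,
                right_label=right_label,
                mediating_repeat=repeat,
                markers=names,
                flags=tuple(flags),
            )
        )
    if not undo_steps and flags:
        events.append(
            InversionEvent(
                name="unresolved", left_bp=0, right_bp=0, size=0,
                flags=tuple(flags),
            )
        )

    # Prefer outermost-first (largest marker set first) whenever that order
    # also replays to the observed permutation (always true for nested
    # histories); otherwise keep the provably replayable order.
    if len(events) > 1:
        outermost = sorted(events, key=lambda e: -len(e.markers))
        try:
            if replay_events(perm, outermost) == perm.order:
                events = outermost
        except ValidationError:
            pass
    for k, ev in enumerate(events, 1):
        ev.name = f"event{k}"
    return events


def _locate_in_record(record, perm, marker_ids):
    """Breakpoint coordinates/labels for a marker set, in the observed genome.

    Nested inversions preserve each segment's genomic extent, so the span
    of the event's markers in the observed record measures the event.
    """
    genes = {f.gene: f for f in record.gene_features()}
    names = [perm.markers[k - 1] for k in marker_ids]
    feats = [genes[g] for g in names if g in genes]
    lo = min(f.start for f in feats)
    hi = max(f.end for f in feats)
    ordered = record.gene_features()
    prev = max((g for g in ordered if g.end <= lo), default=None,
               key=lambda g: g.end)
    nxt = min((g for g in ordered if g.start >= hi), default=None,
              key=lambda g: g.start)
    left_bp = (prev.end + lo) // 2 if prev else lo
    right_bp = (hi + nxt.start) // 2 if nxt else hi
    first = min(feats, key=lambda f: f.start)
    last = max(feats, key=lambda f: f.end)
    left_label = f"IGS({prev.gene if prev else 'ORIGIN'}-{first.gene})"
    right_label = f"IGS({last.gene}-{nxt.gene if nxt else 'ORIGIN'})"
    # a mediating repeat is a planted repeat label inside either flanking gap
    gap_left = (prev.end if prev else 0, lo)
    gap_right = (hi, nxt.start if nxt else len(record.sequence))
    repeat = None
    for lab in record.features:
        if lab.kind != "IGS_label" or not lab.gene.startswith("repeat"):
            continue
        s, e = lab.parts[0]
        for gs, ge in (gap_left, gap_right):
            if s < ge and e > gs:  # overlaps the gap
                repeat = (lab.gene, e - s)
    return left_bp, right_bp, left_label, right_label, repeat


def localize_breakpoints(
    event: InversionEvent, record: PlastomeRecord
) -> InversionEvent:
    """Re-derive flanking-gene labels for an event against *record*."""
    if not event.markers:
        return event

    class _P:  # minimal shim carrying marker names
        markers = tuple(event.markers)

    left_bp, right_bp, ll, rl, repeat = _locate_in_record(
        record, _P, list(range(1, len(event.markers) + 1))
    )
    return InversionEvent(
        name=event.name, left_bp=left_bp, right_bp=right_bp,
        size=right_bp - left_bp, left_label=ll, right_label=rl,
        mediating_repeat=repeat, markers=event.markers, flags=event.flags,
    )


def replay_events(
    perm: SignedPermutation, events: list[InversionEvent]
) -> tuple[int, ...]:
    """Apply inferred events (outermost-first) to the identity order.

    The result must equal the observed permutation; each event's marker set
    is located as a contiguous run in the current state and reversed.
    """
    rank = {name: k + 1 for k, name in enumerate(perm.markers)}
    cur = tuple(range(1, perm.n + 1))
    for ev in events:
        if not ev.markers:
            continue
        ids = {rank[name] for name in ev.markers}
        pos = [k for k, v in enumerate(cur) if abs(v) in ids]
        if pos != list(range(pos[0], pos[0] + len(ids))):
            raise ValidationError(
                f"event {ev.name}: marker set not contiguous during replay"
            )
        i, j = pos[0], pos[0] + len(ids)
        cur = cur[:i] + tuple(-x for x in reversed(cur[i:j])) + cur[j:]
    return cur
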