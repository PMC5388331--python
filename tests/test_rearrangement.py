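import numpy as np
import pytest

from plastomics.errors import MarkerSetError, ValidationError
from plastomics.rearrangement import (
    SignedPermutation,
    infer_inversion_events,
    lcb_decomposition,
    linear_gene_order,
    replay_events,
    reversal_distance_bfs,
    shared_gene_order,
)


def _perm(order):
    n = len(order)
    return SignedPermutation(
        "toy", tuple(order), tuple(f"g{k}" for k in range(1, n + 1))
    )


def _reverse(order, i, j):
    return order[:i] + tuple(-x for x in reversed(order[i:j])) + order[j:]


class TestSharedGeneOrder:
    def test_reference_vs_itself_identity(self, mini_record):
        p = shared_gene_order(mini_record, mini_record, min_ir_len=500)
        assert p.is_identity()

    def test_single_inversion_signature(self, mini_inverted):
        p = shared_gene_order(
            mini_inverted["50"], mini_inverted["ancestral"], min_ir_len=500
        )
        # exactly one contiguous negative run; outside it, identity
        neg = [k for k, v in enumerate(p.order) if v < 0]
        assert neg == list(range(neg[0], neg[-1] + 1))
        segment = p.order[neg[0] : neg[-1] + 1]
        assert list(segment) == [-x for x in range(
            neg[-1] + 1, neg[0], -1
        )]

    def test_triple_history_has_three_events(self, mini_inverted):
        p = shared_gene_order(
            mini_inverted["50+36+24"], mini_inverted["ancestral"],
            min_ir_len=500,
        )
        events = [
            e for e in infer_inversion_events(
                p, record=mini_inverted["50+36+24"], bfs_limit=0
            )
            if e.markers
        ]
        assert len(events) == 3
        assert not any(e.flags for e in events)

    def test_missing_marker_raises(self, mini_record, mini_inverted):
        from plastomics.synth import MutationSpec, mutate_gene

        damaged = mutate_gene(
            mini_record, "rbcL", MutationSpec("WHOLE_GENE_DELETION")
        )
        with pytest.raises(MarkerSetError):
            shared_gene_order(damaged, mini_record, min_ir_len=500)

    def test_ir_copy_removed_once(self, mini_record):
        order = linear_gene_order(mini_record, min_ir_len=500)
        names = [g for g, *_ in order]
        assert names.count("rpl2") == 1  # IR gene present once
        assert names.count("rbcL") == 1


class TestLcbDecomposition:
    def test_identical_permutations_one_block(self):
        p = _perm((1, 2, 3, 4, 5, 6))
        blocks = lcb_decomposition([p, p])
        assert len(blocks) == 1

    def test_single_inversion_three_blocks(self):
        # hand enumeration on 6 markers: inversion of 3..4 breaks the
        # adjacencies (2,3) and (4,5) -> blocks {1,2}, {3,4}, {5,6}
        ident = _perm((1, 2, 3, 4, 5, 6))
        inv = _perm(_reverse((1, 2, 3, 4, 5, 6), 2, 4))
        blocks = lcb_decomposition([ident, inv])
        assert [b.marker_ids for b in blocks] == [(1, 2), (3, 4), (5, 6)]
        assert blocks[1].orientations == {"toy": -1}

    def test_end_touching_inversion_two_blocks(self):
        ident = _perm((1, 2, 3, 4, 5, 6))
        inv = _perm(_reverse((1, 2, 3, 4, 5, 6), 0, 3))
        blocks = lcb_decomposition([ident, inv])
        assert len(blocks) == 2

    def test_four_genome_panel_seven_blocks(self, mini_inverted):
        ref = mini_inverted["ancestral"]
        perms = [
            shared_gene_order(mini_inverted[k], ref, min_ir_len=500)
            for k in ("ancestral", "50", "50+36", "50+36+24")
        ]
        blocks = lcb_decomposition(perms)
        assert len(blocks) == 7

    def test_tiling_and_maximality(self, mini_inverted):
        ref = mini_inverted["ancestral"]
        perms = [
            shared_gene_order(mini_inverted[k], ref, min_ir_len=500)
            for k in ("ancestral", "50+36", "50+36+24")
        ]
        blocks = lcb_decomposition(perms)
        for p in perms:
            covered = sorted(
                i for b in blocks for i in range(*b.intervals[p.taxon])
            )
            assert covered == list(range(p.n))  # tiling
        # maximality: merging adjacent reference blocks breaks conservation
        from plastomics.rearrangement import _adjacencies

        conserved = set.intersection(
            *(_adjacencies(p.order) for p in perms)
        )
        for left, right in zip(blocks, blocks[1:]):
            a, b = left.marker_ids[-1], right.marker_ids[0]
            adj = (a, b) if (a, b) <= (-b, -a) else (-b, -a)
            assert adj not in conserved

    def test_mismatched_marker_sets(self):
        p1 = _perm((1, 2, 3))
        p2 = SignedPermutation("x", (1, 2, 3), ("a", "b", "c"))
        with pytest.raises(MarkerSetError):
            lcb_decomposition([p1, p2])


class TestReversalDistance:
    def test_identity_zero(self):
        assert reversal_distance_bfs((1, 2, 3)) == 0

    def test_full_flip_one(self):
        assert reversal_distance_bfs((-3, -2, -1)) == 1

    def test_size_limit(self):
        with pytest.raises(ValidationError):
            reversal_distance_bfs(tuple(range(1, 12)))

    def test_all_signed_perms_of_4_vs_iddfs_oracle(self):
        import itertools

        def iddfs_distance(order):
            # independent iterative-deepening search
            target = tuple(range(1, len(order) + 1))

            def dfs(cur, depth):
                if cur == target:
                    return True
                if depth == 0:
                    return False
                n = len(cur)
                for i in range(n):
                    for j in range(i + 1, n + 1):
                        nxt = _reverse(cur, i, j)
                        if dfs(nxt, depth - 1):
                            return True
                return False

            d = 0
            while not dfs(order, d):
                d += 1
            return d

        count = 0
        for base in itertools.permutations(range(1, 5)):
            for signs in itertools.product((1, -1), repeat=4):
                order = tuple(b * s for b, s in zip(base, signs))
                if reversal_distance_bfs(order) != iddfs_distance(order):
                    pytest.fail(f"distance mismatch for {order}")
                count += 1
        assert count == 384


class TestInference:
    def test_single_inversion_recovered(self):
        order = _reverse((1, 2, 3, 4, 5, 6), 1, 4)
        p = _perm(order)
        events = [e for e in infer_inversion_events(p) if e.markers]
        assert len(events) == 1
        assert events[0].markers == ("g2", "g3", "g4")

    def test_triple_nested_sizes(self, mini_inverted):
        maackia = mini_inverted["50+36+24"]
        p = shared_gene_order(
            maackia, mini_inverted["ancestral"], min_ir_len=500
        )
        events = [
            e for e in infer_inversion_events(p, record=maackia, bfs_limit=0)
            if e.markers
        ]
        sizes = [e.size for e in events]
        assert sizes == sorted(sizes, reverse=True)  # outermost-first
        planted = [
            mini_inverted["events"][k].size
            for k in ("INV50", "INV36", "INV24")
        ]
        for got, want in zip(sizes, planted):
            assert abs(got - want) / want < 0.15

    def test_breakpoint_labels_and_repeat(self, mini_inverted):
        maackia = mini_inverted["50+36+24"]
        p = shared_gene_order(
            maackia, mini_inverted["ancestral"], min_ir_len=500
        )
        events = [
            e for e in infer_inversion_events(p, record=maackia, bfs_limit=0)
            if e.markers
        ]
        inv24 = events[2]
        assert "trnC" in inv24.left_label + inv24.right_label
        assert "trnF" in inv24.left_label + inv24.right_label
        inv36 = events[1]
        assert inv36.mediating_repeat == ("repeat29", 29)

    def test_transposition_flagged(self):
        p = _perm((1, 3, 2))
        events = infer_inversion_events(p)
        flags = {f for e in events for f in e.flags}
        n_events = len([e for e in events if e.markers])
        assert "UNRESOLVED" in flags or n_events > reversal_distance_bfs(
            (1, 3, 2)
        )

    def test_replay_reproduces_500_random_histories(self):
        rng = np.random.default_rng(12)
        for _ in range(500):
            n = int(rng.integers(4, 11))
            order = tuple(range(1, n + 1))
            for _k in range(int(rng.integers(1, 4))):
                i, j = sorted(rng.integers(0, n + 1, 2))
                if i == j:
                    j = min(n, j + 1)
                order = _reverse(order, i, j)
            p = _perm(order)
            events = [e for e in infer_inversion_events(p) if e.markers]
            assert replay_events(p, events) == order
            assert len(events) == reversal_distance_bfs(order)
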