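"""Bidirectional pair indices: building, buckets, sequence lookups."""

import pytest

from tirpscope import (
    FixedSequence,
    TIRP,
    TemporalRelation as TR,
    backward_lookup,
    build_indices,
    forward_lookup,
    matches_consecutively,
    random_tree,
    scan_lookup,
)
from tirpscope.index import BACKWARD, FORWARD
from tirpscope.io_formats import canonical_json, indices_to_document

from conftest import A, F, H, L, P

SEQ_P7 = FixedSequence((L, F), (TR.BEFORE,))


def all_slices(tree, max_len=3):
    seqs = set()
    for node in tree:
        for m in range(1, max_len + 1):
            for p in range(1, node.size - m + 2):
                seqs.add(FixedSequence.from_tirp_slice(node.tirp, p, m))
    return seqs


class TestBuildIndices:
    def test_toy_bucket_contents(self, toy_indices):
        forward, _ = toy_indices
        nodes = {e.node_id for e in forward.entries(L, F)}
        assert {"P7", "P12", "P13", "P18"} <= nodes

    def test_size_one_tree_has_empty_indices(self):
        tree = random_tree(n_symbols=4, n_nodes=4, max_size=1, seed=0)
        forward, backward = build_indices(tree)
        assert forward.total_entries == backward.total_entries == 0

    def test_entry_count_equals_sum_of_sizes_minus_one(self):
        tree = random_tree(n_symbols=8, n_nodes=200, max_size=5, seed=3)
        forward, backward = build_indices(tree)
        expected = sum(node.size - 1 for node in tree)
        assert forward.total_entries == expected
        assert backward.total_entries == expected
        # build cost is exactly one append per entry per direction
        assert forward.op_count == backward.op_count == expected

    def test_bucket_symmetry(self):
        tree = random_tree(n_symbols=6, n_nodes=120, max_size=5, seed=9)
        forward, backward = build_indices(tree)
        fwd = {
            (a, b, e)
            for a, inner in forward.buckets.items()
            for b, entries in inner.items()
            for e in entries
        }
        bwd = {
            (b, a, e)
            for a, inner in backward.buckets.items()
            for b, entries in inner.items()
            for e in entries
        }
        assert fwd == bwd

    def test_rebuild_is_idempotent(self, toy_tree):
        doc1 = canonical_json(indices_to_document(*build_indices(toy_tree)))
        doc2 = canonical_json(indices_to_document(*build_indices(toy_tree)))
        assert doc1 == doc2


class TestMatchesConsecutively:
    def test_interior_match_position(self, toy_tree):
        p18 = toy_tree["P18"].tirp
        assert matches_consecutively(p18, SEQ_P7) == [2]
        assert p18.relation(1, 3) == TR.BEFORE

    def test_identity_match(self, toy_tree):
        t = toy_tree["P12"].tirp
        seq = FixedSequence.from_tirp_slice(t, 1, t.size)
        assert matches_consecutively(t, seq) == [1]

    def test_order_matters(self, toy_tree):
        assert matches_consecutively(
            toy_tree["P12"].tirp, FixedSequence((F, L), (TR.BEFORE,))
        ) == []

    def test_relation_mismatch_blocks_match(self, toy_tree):
        seq_overlap = FixedSequence((L, F), (TR.OVERLAPS,))
        assert matches_consecutively(toy_tree["P7"].tirp, seq_overlap) == []

    def test_symbols_only_mode_ignores_relations(self, toy_tree):
        seq_overlap = FixedSequence((L, F), (TR.OVERLAPS,))
        assert matches_consecutively(toy_tree["P7"].tirp, seq_overlap, symbols_only=True) == [1]


class TestLookups:
    def test_forward_extensions_of_focus_pattern(self, toy_tree, toy_indices):
        rows = forward_lookup(toy_indices, toy_tree, SEQ_P7)
        assert sorted(r.node_id for r in rows) == ["P12", "P13", "P18"]

    def test_backward_extensions_of_focus_pattern(self, toy_tree, toy_indices):
        rows = backward_lookup(toy_indices, toy_tree, SEQ_P7)
        assert sorted(r.node_id for r in rows) == ["P16", "P18"]
        assert {r.symbol for r in rows} == {P}

    def test_fixed_fall_then_happiness_has_one_backward_row(self, toy_tree, toy_indices):
        seq = FixedSequence((F, H), (TR.BEFORE,))
        rows = backward_lookup(toy_indices, toy_tree, seq)
        assert [(r.node_id, r.symbol) for r in rows] == [("P13", L)]

    def test_fixed_fall_then_happiness_has_no_forward_rows(self, toy_tree, toy_indices):
        seq = FixedSequence((F, H), (TR.BEFORE,))
        assert forward_lookup(toy_indices, toy_tree, seq) == []

    def test_unknown_symbol_gives_empty_result(self, toy_tree, toy_indices):
        seq = FixedSequence(("NoSuch.Symbol",), ())
        assert forward_lookup(toy_indices, toy_tree, seq) == []
        assert backward_lookup(toy_indices, toy_tree, seq) == []

    def test_row_ordering_vs_desc_then_symbol(self, toy_tree, toy_indices):
        rows = forward_lookup(toy_indices, toy_tree, FixedSequence((L,), ()))
        vs = [r.metrics.vs for r in rows]
        assert vs == sorted(vs, reverse=True)

    def test_row_fields_rederivable_from_node(self, toy_tree, toy_indices):
        """symbol, R and X/Y of every row follow from its node's TIRP alone."""
        for seq in all_slices(toy_tree, max_len=2):
            for lookup in (forward_lookup, backward_lookup):
                for row in lookup(toy_indices, toy_tree, seq):
                    t = toy_tree[row.node_id].tirp
                    assert row.symbol == t.symbols[row.position - 1]
                    assert row.size == t.size
                    c_abs = row.match_position + (
                        seq.size - 1 if row.direction == FORWARD else 0
                    )
                    lo, hi = sorted((c_abs, row.position))
                    assert row.relation == t.relation(lo, hi)

    @pytest.mark.parametrize("seed", range(6))
    def test_indexed_lookup_equals_linear_scan(self, seed):
        tree = random_tree(n_symbols=6, n_nodes=80, max_size=5, seed=seed)
        indices = build_indices(tree)
        for seq in all_slices(tree):
            assert forward_lookup(indices, tree, seq) == scan_lookup(tree, seq, FORWARD)
            assert backward_lookup(indices, tree, seq) == scan_lookup(tree, seq, BACKWARD)
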