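"""Session semantics: panels, selection, shifting, undo, and the positional baseline."""

import pytest

from tirpscope import (
    CannotShiftError,
    ExplorationSession,
    FixedSequence,
    TemporalRelation as TR,
    UnknownSymbolError,
    klw_positional_query,
)
from tirpscope.index import BACKWARD, FORWARD

from conftest import A, F, H, L, P


@pytest.fixture()
def session(toy_tree, toy_indices):
    return ExplorationSession(toy_tree, toy_indices)


def row_for(panel, node_id, symbol=None):
    for row in panel:
        if row.node_id == node_id and (symbol is None or row.symbol == symbol):
            return row
    raise AssertionError(f"no row for {node_id}/{symbol}")


class TestStartSession:
    def test_focus_on_fall_event(self, session, toy_tree):
        state = session.start(F)
        assert state.fixed.symbols == (F,)
        assert state.center == 1
        assert state.center_label(toy_tree) == "1/1"
        assert state.left and state.right
        p17 = row_for(state.left, "P17")
        assert p17.symbol == H
        assert p17.relation == TR.OVERLAPS
        assert p17.size_label == "1/4"

    def test_unknown_symbol_reports_near_matches(self, session):
        with pytest.raises(UnknownSymbolError, match="Fall.Event"):
            session.start("Fall.Even")

    def test_isolated_symbol_has_empty_panels(self, toy_tree, toy_indices):
        # prune to a single root to simulate an unextendable symbol
        import tirpscope
        lone = tirpscope.EnumerationTree(alphabet=frozenset((F,)))
        lone.add_node(
            tirpscope.TIRPNode(
                id="P1", tirp=tirpscope.TIRP((F,)), metrics=toy_tree["P1"].metrics
            )
        )
        sess = ExplorationSession(lone, tirpscope.build_indices(lone))
        state = sess.start(F)
        assert state.left == () and state.right == ()


class TestSelection:
    def test_selecting_later_happiness_fixes_sequence(self, session, toy_tree):
        state = session.start(F)
        state = session.select(row_for(state.right, "P13", H))
        assert state.fixed.symbols == (F, H)
        assert state.fixed.relation(1, 2) == TR.BEFORE
        assert state.selected_node == "P13"
        assert state.center_label(toy_tree) == "2/3"
        # the only TIRP with an earlier STI for this sequence is P13 itself
        assert [(r.node_id, r.symbol) for r in state.left] == [("P13", L)]
        # the same-side panel is retained with the chosen row marked
        assert [r.node_id for r in state.right if r.selected] == ["P13"]

    def test_selecting_backward_prepends_and_rebases_center(self, session):
        state = session.start(F)
        state = session.select(row_for(state.left, "P16", L))
        assert state.fixed.symbols == (L, F)
        assert state.center == 2
        assert state.center_symbol == F

    def test_stale_row_rejected(self, session, toy_tree, toy_indices):
        state = session.start(F)
        foreign = row_for(
            ExplorationSession(toy_tree, toy_indices).start(L).right, "P15"
        )
        from tirpscope import StaleSelectionError
        with pytest.raises(StaleSelectionError):
            session.select(foreign)


class TestShifts:
    def test_shift_forward_empties_right_panel(self, session):
        state = session.start(F)
        state = session.select(row_for(state.right, "P13", H))
        state = session.shift_forward()
        assert state.right == ()  # no TIRP extends <Fall, Happiness> later
        assert [(r.node_id, r.symbol, r.selected) for r in state.left] == [
            ("P13", F, True)
        ]

    def test_shifts_never_change_the_fixed_sequence(self, session):
        state = session.start(F)
        state = session.select(row_for(state.right, "P13", H))
        fixed, selected = state.fixed, state.selected_node
        state = session.shift_forward()
        state = session.shift_backward()
        assert state.fixed == fixed and state.selected_node == selected

    def test_boundary_shift_errors(self, session):
        session.start(F)
        with pytest.raises(CannotShiftError):
            session.shift_backward()
        with pytest.raises(CannotShiftError):
            session.shift_forward()  # no later selection exists yet

    def test_interior_center_shows_both_fixed_neighbors(self, session):
        state = session.start(L)
        state = session.select(row_for(state.right, "P18", F))
        state = session.select(row_for(state.left, "P18", P))
        assert state.fixed.symbols == (P, L, F)
        state = session.shift_forward()  # center on L... wait, center was re-based
        assert state.center_symbol == F
        state = session.shift_backward()
        assert state.center_symbol == L
        assert [r.selected for r in state.left] == [True]
        assert [r.selected for r in state.right] == [True]
        assert state.left[0].symbol == P and state.right[0].symbol == F


class TestUndo:
    def test_undo_then_reselect_is_identity(self, session):
        state = session.start(F)
        row = row_for(state.right, "P13", H)
        after = session.select(row)
        session.undo()
        again = session.select(row_for(session.state.right, "P13", H))
        assert again == after

    def test_undo_without_history_errors(self, session):
        session.start(F)
        with pytest.raises(RuntimeError):
            session.undo()


class TestPositionalQuery:
    def test_query_over_returns_relative_to_backward_lookup(self, toy_tree):
        nodes = {n.id for n in klw_positional_query(toy_tree, intermediate=L, last=F)}
        assert {"P16", "P18"} <= nodes  # the true backward extensions
        assert "P15" in nodes  # non-immediate match the user did not want

    def test_first_and_last_on_size_one_node(self, toy_tree):
        nodes = klw_positional_query(toy_tree, first=F, last=F)
        assert "P1" in {n.id for n in nodes}

    def test_intermediate_needs_interior_positions(self):
        from tirpscope import random_tree
        tree = random_tree(n_symbols=4, n_nodes=10, max_size=2, seed=1)
        assert klw_positional_query(tree, intermediate="S00") == []

    def test_requires_an_argument(self, toy_tree):
        with pytest.raises(ValueError):
            klw_positional_query(toy_tree)

    def test_superset_property_on_random_trees(self):
        """Every backward-lookup answer satisfies the corresponding positional
        query: the baseline can only over-return, never under-return."""
        from tirpscope import backward_lookup, build_indices, random_tree
        from tirpscope.index import FixedSequence
        for seed in range(5):
            tree = random_tree(n_symbols=5, n_nodes=50, max_size=4, seed=seed)
            indices = build_indices(tree)
            seqs = set()
            for node in tree:
                for m in (1, 2, 3):
                    for p in range(1, node.size - m + 2):
                        seqs.add(FixedSequence.from_tirp_slice(node.tirp, p, m))
            for seq in seqs:
                hits = {r.node_id for r in backward_lookup(indices, tree, seq)}
                if seq.size == 1:
                    query = klw_positional_query(tree, last=seq.symbols[0])
                else:
                    query = klw_positional_query(
                        tree, intermediate=seq.symbols[0], last=seq.symbols[-1]
                    )
                assert hits <= {n.id for n in query}
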