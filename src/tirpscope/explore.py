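"""Associative exploration sessions over an indexed enumeration tree.

A session starts from a single STI of interest.  Two panels show the
possible extensions: the right panel lists TIRPs containing the fixed
sequence plus a later STI, the left panel those with an earlier STI.
Selecting a row fixes the extended sequence; shifting the focus (Next /
Back) moves the center STI along the fixed sequence without changing it,
exposing further extensions at the boundary.  The center block always
shows the metrics of the most recently selected TIRP, with the size
label X/Y giving the center STI's position X within that size-Y TIRP.

Also provided is the positional query of the earlier-generation KLW
interface (filter patterns by first / intermediate / last symbol), kept
as the comparison baseline: it over-returns relative to a backward
lookup because it cannot express "immediately beforehand".
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

from .core import EnumerationTree, TIRPNode
from .index import (
    BACKWARD,
    FORWARD,
    ExtensionRow,
    FixedSequence,
    PairIndex,
    backward_lookup,
    forward_lookup,
)


class UnknownSymbolError(KeyError):
    pass


class StaleSelectionError(RuntimeError):
    pass


class CannotShiftError(RuntimeError):
    pass


@dataclass(frozen=True)
class ExplorationState:
    """Immutable snapshot of a session: fixed sequence, center, panels."""

    fixed: FixedSequence
    center: int
    selected_node: str
    match_position: int  # where `fixed` sits in the selected node's TIRP
    left: Tuple[ExtensionRow, ...]
    right: Tuple[ExtensionRow, ...]

    @property
    def center_symbol(self) -> str:
        return self.fixed.symbols[self.center - 1]

    def center_label(self, tree: EnumerationTree) -> str:
        """Size label X/Y of the center block: center position within the selected TIRP."""
        node = tree[self.selected_node]
        return f"{self.match_position + self.center - 1}/{node.size}"


class ExplorationSession:
    """Stateful wrapper: holds the tree, the indices, history for undo."""

    def __init__(
        self,
        tree: EnumerationTree,
        indices: Tuple[PairIndex, PairIndex],
        row_limit: Optional[int] = None,
    ):
        self.tree = tree
        self.indices = indices
        self.row_limit = row_limit
        self.state: Optional[ExplorationState] = None
        self._history: List[ExplorationState] = []

    # -- session operations -------------------------------------------------

    def start(self, symbol: str) -> ExplorationState:
        """Begin at a single STI of interest; it must be a frequent size-1 TIRP."""
        root = None
        for rid in self.tree.roots:
            if self.tree[rid].tirp.symbols == (symbol,):
                root = self.tree[rid]
                break
        if root is None:
            near = difflib.get_close_matches(symbol, sorted(self.tree.alphabet), n=3)
            raise UnknownSymbolError(
                f"{symbol!r} is not a frequent STI in this tree"
                + (f"; nearest symbols: {near}" if near else "")
            )
        seq = FixedSequence((symbol,), (), provenance=(root.id,))
        state = ExplorationState(
            fixed=seq,
            center=1,
            selected_node=root.id,
            match_position=1,
            left=tuple(
                backward_lookup(self.indices, self.tree, seq, center=1, limit=self.row_limit)
            ),
            right=tuple(
                forward_lookup(self.indices, self.tree, seq, center=1, limit=self.row_limit)
            ),
        )
        self.state = state
        self._history = []
        return state

    def _require_state(self) -> ExplorationState:
        if self.state is None:
            raise RuntimeError("session not started")
        return self.state

    def select(self, row: ExtensionRow) -> ExplorationState:
        """Fix the sequence extended by this panel row's STI.

        The new element's relations to every fixed element are read from
        the row's TIRP, so the enlarged sequence carries a complete
        sub-matrix.  The opposite panel is recomputed against the
        enlarged sequence; the row's own panel is retained with the row
        marked.
        """
        state = self._require_state()
        panel = state.right if row.direction == FORWARD else state.left
        if not any(
            r.node_id == row.node_id and r.position == row.position for r in panel
        ):
            raise StaleSelectionError(
                f"row ({row.node_id}, position {row.position}) is not in the "
                f"current {row.direction} panel"
            )
        node = self.tree[row.node_id]
        m = state.fixed.size
        if row.direction == FORWARD:
            new_start = row.match_position
            new_center = state.center
        else:
            new_start = row.position  # = match_position - 1
            new_center = state.center + 1  # re-based after prepending
        new_fixed = FixedSequence.from_tirp_slice(
            node.tirp,
            new_start,
            m + 1,
            provenance=state.fixed.provenance + (row.node_id,),
        )
        marked_panel = tuple(
            r.marked() if (r.node_id == row.node_id and r.position == row.position) else replace(r, selected=False)
            for r in panel
        )
        if row.direction == FORWARD:
            left = tuple(
                backward_lookup(
                    self.indices, self.tree, new_fixed, center=new_center, limit=self.row_limit
                )
            )
            right = marked_panel
        else:
            left = marked_panel
            right = tuple(
                forward_lookup(
                    self.indices, self.tree, new_fixed, center=new_center, limit=self.row_limit
                )
            )
        new_state = ExplorationState(
            fixed=new_fixed,
            center=new_center,
            selected_node=row.node_id,
            match_position=new_start,
            left=left,
            right=right,
        )
        self._history.append(state)
        self.state = new_state
        return new_state

    def _neighbor_row(self, state: ExplorationState, direction: str, center: int) -> ExtensionRow:
        """The single marked row showing an already-fixed neighbour of the center."""
        node = self.tree[state.selected_node]
        q_seq = center - 1 if direction == BACKWARD else center + 1
        q = state.match_position + q_seq - 1
        c_abs = state.match_position + center - 1
        assert node.metrics is not None
        return ExtensionRow(
            direction=direction,
            symbol=state.fixed.symbols[q_seq - 1],
            relation=node.tirp.relation(min(c_abs, q), max(c_abs, q)),
            node_id=node.id,
            position=q,
            match_position=state.match_position,
            size=node.size,
            metrics=node.metrics,
            selected=True,
        )

    def _shift(self, delta: int) -> ExplorationState:
        state = self._require_state()
        c = state.center + delta
        m = state.fixed.size
        if not (1 <= c <= m):
            raise CannotShiftError(
                "cannot shift "
                + ("forward: no later selection exists" if delta > 0 else "backward: already at the first fixed STI")
            )
        if c > 1:
            left: Tuple[ExtensionRow, ...] = (self._neighbor_row(state, BACKWARD, c),)
        else:
            left = tuple(
                backward_lookup(
                    self.indices, self.tree, state.fixed, center=c, limit=self.row_limit
                )
            )
        if c < m:
            right: Tuple[ExtensionRow, ...] = (self._neighbor_row(state, FORWARD, c),)
        else:
            right = tuple(
                forward_lookup(
                    self.indices, self.tree, state.fixed, center=c, limit=self.row_limit
                )
            )
        new_state = replace(state, center=c, left=left, right=right)
        self._history.append(state)
        self.state = new_state
        return new_state

    def shift_forward(self) -> ExplorationState:
        """Move the focus one STI later along the fixed sequence (Next)."""
        return self._shift(+1)

    def shift_backward(self) -> ExplorationState:
        """Move the focus one STI earlier along the fixed sequence (Back)."""
        return self._shift(-1)

    def undo(self) -> ExplorationState:
        """Pop the last selection or shift."""
        if not self._history:
            raise RuntimeError("nothing to undo")
        self.state = self._history.pop()
        return self.state

    def reset(self, symbol: Optional[str] = None) -> ExplorationState:
        """Restart from a symbol (default: the current first fixed symbol)."""
        state = self._require_state()
        return self.start(symbol if symbol is not None else state.fixed.symbols[0])


def klw_positional_query(
    tree: EnumerationTree,
    first: Optional[str] = None,
    intermediate: Optional[str] = None,
    last: Optional[str] = None,
) -> List[TIRPNode]:
    """Positional pattern filter in the style of the KLW baseline interface.

    ``first`` anchors position 1.  ``intermediate`` and ``last`` match at
    strictly increasing later positions (``intermediate`` strictly between
    its given neighbours).  Because the query cannot say "immediately
    before", it over-returns relative to a backward lookup of a
    consecutive sequence: every backward-lookup result also satisfies the
    corresponding positional query.
    """
    if first is None and intermediate is None and last is None:
        raise ValueError("at least one of first/intermediate/last must be given")
    out = []
    for node in tree:
        symbols = node.tirp.symbols
        k = node.size
        if first is not None and symbols[0] != first:
            continue
        if intermediate is not None:
            # strictly interior positions (1-based 2..k-1)
            inter_pos = [i for i in range(1, k - 1) if symbols[i] == intermediate]
            if last is not None:
                if not any(
                    symbols[j] == last for i in inter_pos for j in range(i + 1, k)
                ):
                    continue
            elif not inter_pos:
                continue
        elif last is not None:
            # "immediately at the end" is inexpressible; any occurrence matches
            if last not in symbols:
                continue
        out.append(node)
    return out
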