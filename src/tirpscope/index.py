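"""Bidirectional pair indexing of an enumeration tree.

One pass over the tree records, for every consecutive position pair
(i, i+1) of every TIRP, an entry in two nested maps: the forward index
keyed (earlier symbol -> later symbol) and the backward index keyed
(later symbol -> earlier symbol).  Total work and space are proportional
to the sum of (size - 1) over all N nodes, i.e. O(N * Lmax) entries over
an O(M * M) key grid for an alphabet of M symbols.

Lookups then answer: given a fixed sequence of STIs (symbols plus their
relation sub-matrix), which TIRPs contain it consecutively with at least
one additional STI afterwards (forward) or beforehand (backward)?
Candidates are gathered from the pair buckets (rarest bucket first for
multi-pair sequences) and verified against the full sub-matrix, so the
index is purely an accelerator: results equal a linear scan of the tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .core import EnumerationTree, TIRP, TIRPMetrics, TemporalRelation, pair_index

logger = logging.getLogger(__name__)

FORWARD = "forward"
BACKWARD = "backward"


@dataclass(frozen=True)
class IndexEntry:
    """One consecutive symbol pair occurrence: TIRP node, 1-based position of the pair's first element, and their relation."""

    node_id: str
    position: int
    relation: TemporalRelation


@dataclass
class PairIndex:
    """Nested map symbol -> symbol -> entries, for one exploration direction."""

    direction: str
    buckets: Dict[str, Dict[str, List[IndexEntry]]] = field(default_factory=dict)
    op_count: int = 0  # number of entry appends; the operational cost of building

    def add(self, key1: str, key2: str, entry: IndexEntry) -> None:
        self.buckets.setdefault(key1, {}).setdefault(key2, []).append(entry)
        self.op_count += 1

    def entries(self, key1: str, key2: str) -> List[IndexEntry]:
        return self.buckets.get(key1, {}).get(key2, [])

    @property
    def total_entries(self) -> int:
        return sum(
            len(entries)
            for inner in self.buckets.values()
            for entries in inner.values()
        )


def build_indices(tree: EnumerationTree) -> Tuple[PairIndex, PairIndex]:
    """Build the forward and backward pair indices in a single pass.

    For every node and every consecutive pair (s_i, s_{i+1}) the same
    entry lands in forward[s_i][s_{i+1}] and backward[s_{i+1}][s_i], so
    the two indices hold identical entry sets under transposed keys.
    Entries are appended in (node insertion order, position) order.
    An empty tree yields two empty indices.
    """
    forward = PairIndex(FORWARD)
    backward = PairIndex(BACKWARD)
    for node in tree:
        symbols = node.tirp.symbols
        for i in range(1, node.size):
            entry = IndexEntry(node.id, i, node.tirp.relation(i, i + 1))
            forward.add(symbols[i - 1], symbols[i], entry)
            backward.add(symbols[i], symbols[i - 1], entry)
    return forward, backward


@dataclass(frozen=True)
class FixedSequence:
    """A user-fixed run of STIs: symbols plus their full relation sub-matrix.

    ``relations`` uses the same column-major upper-triangular layout as
    :class:`~tirpscope.core.TIRP`; an entry may be ``None`` to leave that
    pair unconstrained (used by chain-style queries that specify only
    consecutive relations).  ``provenance`` records the node ids the
    selections were taken from.
    """

    symbols: Tuple[str, ...]
    relations: Tuple[Optional[TemporalRelation], ...] = ()
    provenance: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = len(self.symbols)
        if m < 1:
            raise ValueError("a fixed sequence needs at least one symbol")
        if len(self.relations) != m * (m - 1) // 2:
            raise ValueError("relation sub-matrix has the wrong number of entries")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def relation(self, i: int, j: int) -> Optional[TemporalRelation]:
        return self.relations[pair_index(i, j)]

    @classmethod
    def from_tirp_slice(
        cls, tirp: TIRP, start: int, length: int, provenance: Tuple[str, ...] = ()
    ) -> "FixedSequence":
        """The sub-sequence of ``tirp`` at 1-based ``start`` with its sub-matrix."""
        if not (1 <= start and start + length - 1 <= tirp.size):
            raise IndexError("slice out of range")
        symbols = tirp.symbols[start - 1 : start + length - 1]
        rels = []
        for j in range(2, length + 1):
            for i in range(1, j):
                rels.append(tirp.relation(start + i - 1, start + j - 1))
        return cls(symbols, tuple(rels), provenance)


def matches_at(t: TIRP, seq: FixedSequence, p: int, symbols_only: bool = False) -> bool:
    """Does ``seq`` match ``t`` at 1-based position ``p`` (consecutively)?"""
    m = seq.size
    if not (1 <= p and p + m - 1 <= t.size):
        return False
    if t.symbols[p - 1 : p + m - 1] != seq.symbols:
        return False
    if symbols_only:
        return True
    for j in range(2, m + 1):
        for i in range(1, j):
            want = seq.relation(i, j)
            if want is not None and t.relation(p + i - 1, p + j - 1) != want:
                return False
    return True


def matches_consecutively(
    t: TIRP, seq: FixedSequence, symbols_only: bool = False
) -> List[int]:
    """All 1-based positions at which ``seq`` occurs consecutively in ``t``."""
    return [
        p
        for p in range(1, t.size - seq.size + 2)
        if matches_at(t, seq, p, symbols_only)
    ]


@dataclass(frozen=True)
class ExtensionRow:
    """One panel row: an extending STI with the TIRP it comes from.

    ``position`` is X of the size label X/Y: the 1-based location of the
    extending STI within the TIRP of ``size`` Y.  ``relation`` is R, the
    Allen relation between the exploration's center STI and the extending
    STI, read from the TIRP's full matrix (the two need not be adjacent).
    ``match_position`` is where the fixed sequence matched in the TIRP.
    """

    direction: str
    symbol: str
    relation: TemporalRelation
    node_id: str
    position: int
    match_position: int
    size: int
    metrics: TIRPMetrics
    selected: bool = False

    @property
    def size_label(self) -> str:
        return f"{self.position}/{self.size}"

    def marked(self) -> "ExtensionRow":
        return replace(self, selected=True)


def _check_alphabet(tree: EnumerationTree, seq: FixedSequence) -> bool:
    unknown = [s for s in seq.symbols if s not in tree.alphabet]
    if unknown:
        logger.warning("sequence symbols not in tree alphabet: %s", unknown)
        return False
    return True


def _candidates(
    indices: Tuple[PairIndex, PairIndex],
    seq: FixedSequence,
    direction: str,
) -> List[Tuple[str, int]]:
    """Candidate (node id, match position) pairs from the pair buckets."""
    forward, backward = indices
    if seq.size == 1:
        sym = seq.symbols[0]
        if direction == FORWARD:
            # every entry with sym as the pair's first element: sym at a
            # non-final position, i.e. it has a later STI.
            return [
                (e.node_id, e.position)
                for inner in [forward.buckets.get(sym, {})]
                for entries in inner.values()
                for e in entries
            ]
        return [
            (e.node_id, e.position + 1)
            for inner in [backward.buckets.get(sym, {})]
            for entries in inner.values()
            for e in entries
        ]
    # Rarest consecutive pair bucket first, then verify the full sub-matrix.
    best: Optional[Tuple[int, int, List[IndexEntry]]] = None
    for j in range(1, seq.size):
        a, b = seq.symbols[j - 1], seq.symbols[j]
        entries = (
            forward.entries(a, b) if direction == FORWARD else backward.entries(b, a)
        )
        want = seq.relation(j, j + 1)
        if want is not None:
            entries = [e for e in entries if e.relation == want]
        if best is None or len(entries) < best[0]:
            best = (len(entries), j, entries)
    assert best is not None
    _, j, entries = best
    return [(e.node_id, e.position - j + 1) for e in entries]


def _lookup(
    indices: Tuple[PairIndex, PairIndex],
    tree: EnumerationTree,
    seq: FixedSequence,
    direction: str,
    center: Optional[int],
    symbols_only: bool,
    limit: Optional[int],
) -> List[ExtensionRow]:
    if not _check_alphabet(tree, seq):
        return []
    m = seq.size
    if center is None:
        center = m if direction == FORWARD else 1
    if not (1 <= center <= m):
        raise IndexError(f"center {center} out of range for a size-{m} sequence")
    rows: Dict[Tuple[str, int], ExtensionRow] = {}
    for node_id, p in _candidates(indices, seq, direction):
        node = tree[node_id]
        if not matches_at(node.tirp, seq, p, symbols_only):
            continue
        if direction == FORWARD:
            if p + m - 1 >= node.size:
                continue
            q = p + m
        else:
            if p <= 1:
                continue
            q = p - 1
        key = (node_id, q)
        if key in rows:
            continue
        c_abs = p + center - 1
        rel = node.tirp.relation(min(c_abs, q), max(c_abs, q))
        if node.metrics is None:
            raise ValueError(f"node {node_id!r} has no metrics; panels need them")
        rows[key] = ExtensionRow(
            direction=direction,
            symbol=node.tirp.symbols[q - 1],
            relation=rel,
            node_id=node_id,
            position=q,
            match_position=p,
            size=node.size,
            metrics=node.metrics,
        )
    ordered = sorted(
        rows.values(), key=lambda r: (-r.metrics.vs, r.symbol, r.node_id)
    )
    return ordered[:limit] if limit is not None else ordered


def forward_lookup(
    indices: Tuple[PairIndex, PairIndex],
    tree: EnumerationTree,
    seq: FixedSequence,
    center: Optional[int] = None,
    symbols_only: bool = False,
    limit: Optional[int] = None,
) -> List[ExtensionRow]:
    """TIRPs containing ``seq`` consecutively plus at least one STI afterwards.

    One row per (node, extending position); rows ordered by vertical
    support descending, then symbol, then node id.  ``center`` is the
    1-based index within ``seq`` of the exploration's center STI, used to
    fill each row's R (defaults to the last fixed element).
    """
    return _lookup(indices, tree, seq, FORWARD, center, symbols_only, limit)


def backward_lookup(
    indices: Tuple[PairIndex, PairIndex],
    tree: EnumerationTree,
    seq: FixedSequence,
    center: Optional[int] = None,
    symbols_only: bool = False,
    limit: Optional[int] = None,
) -> List[ExtensionRow]:
    """TIRPs containing ``seq`` consecutively plus at least one STI beforehand."""
    return _lookup(indices, tree, seq, BACKWARD, center, symbols_only, limit)


def scan_lookup(
    tree: EnumerationTree,
    seq: FixedSequence,
    direction: str,
    center: Optional[int] = None,
    symbols_only: bool = False,
) -> List[ExtensionRow]:
    """Index-free reference lookup: linear scan of every node.

    Answers the same question as :func:`forward_lookup` /
    :func:`backward_lookup` using only :func:`matches_consecutively`;
    kept as the slow reference path the indexed lookups are checked
    against.
    """
    m = seq.size
    if center is None:
        center = m if direction == FORWARD else 1
    rows: Dict[Tuple[str, int], ExtensionRow] = {}
    for node in tree:
        for p in matches_consecutively(node.tirp, seq, symbols_only):
            if direction == FORWARD:
                if p + m - 1 >= node.size:
                    continue
                q = p + m
            else:
                if p <= 1:
                    continue
                q = p - 1
            key = (node.id, q)
            if key in rows:
                continue
            c_abs = p + center - 1
            rel = node.tirp.relation(min(c_abs, q), max(c_abs, q))
            assert node.metrics is not None
            rows[key] = ExtensionRow(
                direction=direction,
                symbol=node.tirp.symbols[q - 1],
                relation=rel,
                node_id=node.id,
                position=q,
                match_position=p,
                size=node.size,
                metrics=node.metrics,
            )
    return sorted(rows.values(), key=lambda r: (-r.metrics.vs, r.symbol, r.node_id))
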