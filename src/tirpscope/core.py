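"""Core domain model for time-interval-related pattern (TIRP) analysis.

The atoms are symbolic time intervals (STIs): a symbol such as
``"Glucose.High"`` holding over a closed time interval ``[start, end]``.
A TIRP is a lexicographically ordered sequence of STI symbols together
with a conjunction of Allen temporal relations between every pair of
STIs, stored as an upper-triangular (Hoeppner) matrix.  Because the STIs
of an instance are totally ordered by ``sti_order``, the seven
non-inverse Allen relations (before, meets, overlaps, starts, contains,
finished-by, equals) suffice to describe any pair.

Times are abstract numbers; the granularity (months, days, ...) is a
property of the input data, never of this module.  Zero-duration STIs
(``start == end``) are legal and represent instantaneous events such as
a logged fall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple


class TemporalRelation(Enum):
    """The seven non-inverse Allen relations, each with a one-character code."""

    BEFORE = "b"
    MEETS = "m"
    OVERLAPS = "o"
    STARTS = "s"
    CONTAINS = "c"
    FINISHED_BY = "f"
    EQUALS = "e"

    @classmethod
    def from_code(cls, code: str) -> "TemporalRelation":
        try:
            return cls(code)
        except ValueError:
            raise ValueError(f"unknown temporal relation code {code!r}") from None

    def __repr__(self) -> str:  # compact in test diffs
        return f"<{self.name}>"


#: Sentinel outcome of :func:`allen_relation` when two intervals are separated
#: by more than the maximal gap: the pair carries no usable relation and any
#: candidate pattern instance containing it is invalid.
UNRELATED = None


@dataclass(frozen=True)
class STI:
    """A symbolic time interval: ``symbol`` holds over the closed ``[start, end]``."""

    symbol: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise ValueError("STI symbol must be a non-empty, non-whitespace string")
        if self.start > self.end:
            raise ValueError(
                f"STI start must not exceed end (got {self.start} > {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    def shifted(self, delta: float) -> "STI":
        return STI(self.symbol, self.start + delta, self.end + delta)

    def sort_key(self) -> Tuple[float, float, str]:
        return (self.start, self.end, self.symbol)


def sti_order(a: STI, b: STI) -> int:
    """Total lexicographic order on STIs by (start, end, symbol); -1/0/+1."""
    ka, kb = a.sort_key(), b.sort_key()
    if ka < kb:
        return -1
    if ka > kb:
        return 1
    return 0


def allen_relation(
    a: STI,
    b: STI,
    epsilon: float = 0.0,
    max_gap: float = math.inf,
) -> Optional[TemporalRelation]:
    """Allen relation of ``a`` towards ``b``, where ``a`` precedes ``b`` lexicographically.

    Timestamps within ``epsilon`` of each other are treated as equal, so
    the boundary between e.g. MEETS and OVERLAPS is robust to timestamp
    noise.  A BEFORE pair whose gap ``b.start - a.end`` exceeds
    ``max_gap`` yields :data:`UNRELATED` (``None``); the maximal-gap
    constraint binds the relation itself, not only adjacent pattern
    positions.  Exactly one outcome is returned for any legal pair.
    """
    if sti_order(a, b) > 0:
        raise ValueError("allen_relation requires sti_order(a, b) <= 0")

    def eq(x: float, y: float) -> bool:
        return abs(x - y) <= epsilon

    if eq(a.start, b.start) and eq(a.end, b.end):
        return TemporalRelation.EQUALS
    if eq(a.start, b.start):
        return TemporalRelation.STARTS  # a.end < b.end by ordering
    if eq(a.end, b.end):
        return TemporalRelation.FINISHED_BY  # a.start < b.start by ordering
    if eq(a.end, b.start):
        return TemporalRelation.MEETS
    if a.end < b.start:
        gap = b.start - a.end
        return TemporalRelation.BEFORE if gap <= max_gap else UNRELATED
    if b.end < a.end:
        return TemporalRelation.CONTAINS
    return TemporalRelation.OVERLAPS


def pair_index(i: int, j: int) -> int:
    """Flat index of pair ``(i, j)``, 1-based, ``i < j``, in column-major order.

    Pairs are stored as (1,2), (1,3), (2,3), (1,4), (2,4), (3,4), ...;
    extending a pattern by one STI appends one whole new column, so a
    parent's relation vector is always a prefix of its child's.
    """
    if not (1 <= i < j):
        raise IndexError(f"invalid pair ({i}, {j})")
    return (j - 1) * (j - 2) // 2 + (i - 1)


@dataclass(frozen=True)
class TIRP:
    """A time-interval-related pattern: symbols plus a full pairwise relation matrix."""

    symbols: Tuple[str, ...]
    relations: Tuple[TemporalRelation, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.symbols)
        if k < 1:
            raise ValueError("a TIRP needs at least one symbol")
        expected = k * (k - 1) // 2
        if len(self.relations) != expected:
            raise ValueError(
                f"size-{k} TIRP needs {expected} pairwise relations, "
                f"got {len(self.relations)}"
            )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def relation(self, i: int, j: int) -> TemporalRelation:
        """Relation between positions ``i`` and ``j`` (1-based, ``i < j``)."""
        if not (1 <= i < j <= self.size):
            raise IndexError(
                f"pair ({i}, {j}) out of range for size-{self.size} TIRP"
            )
        return self.relations[pair_index(i, j)]

    @property
    def relation_string(self) -> str:
        return "".join(r.value for r in self.relations)

    def extend(self, symbol: str, column: Sequence[TemporalRelation]) -> "TIRP":
        """Child TIRP: one appended symbol plus its relation column."""
        if len(column) != self.size:
            raise ValueError("relation column length must equal current size")
        return TIRP(self.symbols + (symbol,), self.relations + tuple(column))

    def __str__(self) -> str:
        if self.size == 1:
            return f"<{self.symbols[0]}>"
        parts = [self.symbols[0]]
        for j in range(2, self.size + 1):
            parts.append(self.relation(j - 1, j).value)
            parts.append(self.symbols[j - 1])
        return "<" + " ".join(parts) + ">"


def pair_relation(t: TIRP, i: int, j: int) -> TemporalRelation:
    """Module-level alias of :meth:`TIRP.relation` (pure matrix lookup)."""
    return t.relation(i, j)


@dataclass(frozen=True)
class TIRPInstance:
    """One occurrence of a TIRP inside a transaction.

    ``stis`` are the matched intervals in lexicographic order; ``positions``
    (when available) are their 0-based indices in the transaction's sorted
    STI list.
    """

    transaction_id: str
    stis: Tuple[STI, ...]
    positions: Optional[Tuple[int, ...]] = None

    @property
    def earliest_start(self) -> float:
        return min(s.start for s in self.stis)

    @property
    def latest_end(self) -> float:
        return max(s.end for s in self.stis)

    @property
    def duration(self) -> float:
        """Instance span: latest interval end minus earliest start."""
        return self.latest_end - self.earliest_start


def validate_instance(
    t: TIRP,
    inst: TIRPInstance,
    epsilon: float = 0.0,
    max_gap: float = math.inf,
) -> bool:
    """True iff the instance's symbols and all pairwise relations match ``t``."""
    if len(inst.stis) != t.size:
        return False
    for pos, sti in enumerate(inst.stis):
        if sti.symbol != t.symbols[pos]:
            return False
    for j in range(2, t.size + 1):
        for i in range(1, j):
            rel = allen_relation(inst.stis[i - 1], inst.stis[j - 1], epsilon, max_gap)
            if rel is UNRELATED or rel != t.relation(i, j):
                return False
    return True


@dataclass
class Transaction:
    """One entity's STI series (e.g. a patient admission or a resident record)."""

    id: str
    stis: Tuple[STI, ...]
    attributes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stis = tuple(sorted(self.stis, key=STI.sort_key))

    @property
    def symbols(self) -> frozenset:
        return frozenset(s.symbol for s in self.stis)


@dataclass
class STIDatabase:
    """A database of transactions plus the symbol alphabet."""

    transactions: List[Transaction]
    alphabet: frozenset = frozenset()

    def __post_init__(self) -> None:
        seen = set()
        for txn in self.transactions:
            if txn.id in seen:
                raise ValueError(f"duplicate transaction id {txn.id!r}")
            seen.add(txn.id)
        observed = frozenset(
            s.symbol for txn in self.transactions for s in txn.stis
        )
        if not self.alphabet:
            self.alphabet = observed
        elif not observed <= self.alphabet:
            raise ValueError(
                "declared alphabet is missing observed symbols: "
                f"{sorted(observed - self.alphabet)}"
            )

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[Transaction]:
        return iter(self.transactions)

    def transaction(self, txn_id: str) -> Transaction:
        for txn in self.transactions:
            if txn.id == txn_id:
                return txn
        raise KeyError(txn_id)


@dataclass(frozen=True)
class TIRPMetrics:
    """Support metrics of a frequent TIRP.

    vs
        Vertical support: number of transactions containing at least one
        instance.
    relative_vs
        ``vs`` divided by the database size, in [0, 1].
    mhs
        Mean horizontal support: mean, over supporting transactions, of
        the per-transaction instance count (>= 1 whenever vs >= 1).
    mmd
        Mean mean duration: mean, over supporting transactions, of the
        per-transaction mean instance span (two-level average,
        transactions weighted equally).
    size
        Number of STIs in the pattern.
    """

    vs: int
    relative_vs: float
    mhs: float
    mmd: float
    size: int

    def value(self, name: str) -> float:
        if name not in ("vs", "relative_vs", "mhs", "mmd", "size"):
            raise ValueError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclass
class TIRPNode:
    """A node of the enumeration tree: a frequent TIRP with its metrics."""

    id: str
    tirp: TIRP
    metrics: Optional[TIRPMetrics] = None
    supporting: Tuple[str, ...] = ()
    instances: Optional[Dict[str, Tuple[TIRPInstance, ...]]] = None
    parent: Optional[str] = None
    children: List[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.tirp.size


class EnumerationTree:
    """Rooted forest of frequent TIRPs; level k holds the size-k patterns.

    Nodes are kept in insertion order, and a parent is always inserted
    before its children, so serialisation order is a valid topological
    order.
    """

    def __init__(self, alphabet: frozenset = frozenset(), config: Optional[dict] = None):
        self.nodes: Dict[str, TIRPNode] = {}
        self.roots: List[str] = []
        self.alphabet = frozenset(alphabet)
        self.config = dict(config or {})

    @property
    def n(self) -> int:
        """Number of frequent patterns in the tree."""
        return len(self.nodes)

    @property
    def lmax(self) -> int:
        return max((node.size for node in self.nodes.values()), default=0)

    def add_node(self, node: TIRPNode) -> TIRPNode:
        if node.id in self.nodes:
            raise ValueError(f"duplicate node id {node.id!r}")
        if node.parent is None:
            if node.size != 1:
                raise ValueError("root nodes must hold size-1 TIRPs")
            self.roots.append(node.id)
        else:
            if node.parent not in self.nodes:
                raise ValueError(
                    f"parent {node.parent!r} of {node.id!r} not inserted yet"
                )
            parent = self.nodes[node.parent]
            if node.tirp.symbols[:-1] != parent.tirp.symbols:
                raise ValueError(
                    f"node {node.id!r}: symbols are not the parent's plus one appended"
                )
            if node.tirp.relations[: len(parent.tirp.relations)] != parent.tirp.relations:
                raise ValueError(
                    f"node {node.id!r}: relation matrix does not extend the parent's"
                )
            parent.children.append(node.id)
        self.nodes[node.id] = node
        self.alphabet = self.alphabet | frozenset(node.tirp.symbols)
        return node

    def __getitem__(self, node_id: str) -> TIRPNode:
        return self.nodes[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __iter__(self) -> Iterator[TIRPNode]:
        return iter(self.nodes.values())

    def find(self, tirp: TIRP) -> Optional[TIRPNode]:
        """Locate the node holding exactly this TIRP, if frequent."""
        for node in self.nodes.values():
            if node.tirp == tirp:
                return node
        return None

    def validate(self) -> None:
        """Raise ValueError on any structural defect (used as a test oracle)."""
        for rid in self.roots:
            if self.nodes[rid].size != 1:
                raise ValueError(f"root {rid!r} is not size 1")
        seen: set = set()
        for node_id, node in self.nodes.items():
            if node.parent is not None and node.parent not in seen:
                raise ValueError(f"parent of {node_id!r} does not precede it")
            seen.add(node_id)
            k = node.size
            if len(node.tirp.relations) != k * (k - 1) // 2:
                raise ValueError(f"node {node_id!r} has a malformed relation matrix")
            if node.metrics is not None and node.parent is not None:
                parent = self.nodes[node.parent]
                if parent.metrics is not None and node.metrics.vs > parent.metrics.vs:
                    raise ValueError(
                        f"anti-monotonicity violated at edge {node.parent!r} -> {node_id!r}"
                    )
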