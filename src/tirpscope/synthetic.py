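"""Synthetic inputs: planted-pattern STI databases, random trees, and the toy tree.

The planted-pattern generator emulates the structure of clinical STI
databases (which are private in practice): each transaction receives,
with probability ``rate``, a rigidly time-shifted copy of a concrete
template realising a target TIRP, plus background noise intervals drawn
from a disjoint symbol pool.  Rigid shifts preserve every pairwise
relation exactly, so the planted pattern's true vertical support equals
the number of planted transactions.

``fig1_fixture`` builds a fixed 18-node toy enumeration tree over
care-home style symbols (fluids, falls, appetite, happiness, physical
activity) whose forward/backward extension structure matches the
canonical worked example used throughout the tests.  ``random_tree``
grows structurally valid trees of arbitrary size for index fuzzing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    STI,
    EnumerationTree,
    STIDatabase,
    TIRP,
    TIRPMetrics,
    TIRPNode,
    TemporalRelation,
    Transaction,
    UNRELATED,
    allen_relation,
    sti_order,
)

_REL = {r.value: r for r in TemporalRelation}


@dataclass
class PlantSpec:
    """Recipe for a planted-pattern STI database.

    template: concrete STIs realising the target pattern (sorted
    lexicographically; their pairwise relations define the planted TIRP).
    rate: fraction of transactions receiving the template (0 allowed:
    pure-noise database).
    n: number of transactions.
    shift_range: uniform range of the rigid per-transaction time shift.
    noise_mean: Poisson mean of background STIs per transaction.
    noise_symbols: background symbol pool (keep disjoint from the
    template's symbols to make the planted support exact).
    noise_start_range / noise_duration_range: uniform ranges for noise
    interval placement.
    max_gap: gap bound used when deriving the template's relation matrix.
    target: optional expected TIRP; a mismatch with the template's
    realised relations raises at construction.
    """

    template: Tuple[STI, ...]
    rate: float = 0.6
    n: int = 200
    shift_range: Tuple[float, float] = (0.0, 100.0)
    noise_mean: float = 3.0
    noise_symbols: Tuple[str, ...] = ()
    noise_start_range: Tuple[float, float] = (0.0, 60.0)
    noise_duration_range: Tuple[float, float] = (1.0, 5.0)
    max_gap: float = math.inf
    epsilon: float = 0.0
    target: Optional[TIRP] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("rate must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        self.template = tuple(sorted(self.template, key=STI.sort_key))
        self.tirp = self._derive_tirp()
        if self.target is not None and self.tirp != self.target:
            raise ValueError(
                f"template realises {self.tirp}, not the requested target {self.target}"
            )

    def _derive_tirp(self) -> TIRP:
        k = len(self.template)
        if k < 1:
            raise ValueError("template needs at least one STI")
        rels: List[TemporalRelation] = []
        for j in range(2, k + 1):
            for i in range(1, j):
                rel = allen_relation(
                    self.template[i - 1], self.template[j - 1], self.epsilon, self.max_gap
                )
                if rel is UNRELATED:
                    raise ValueError(
                        f"template STIs {i} and {j} are further apart than max_gap; "
                        "the template violates its own matrix"
                    )
                rels.append(rel)
        return TIRP(tuple(s.symbol for s in self.template), tuple(rels))


@dataclass
class GroundTruth:
    """What was actually planted: the pattern and exactly where."""

    tirp: TIRP
    planted_ids: Tuple[str, ...]
    n: int

    @property
    def empirical_rate(self) -> float:
        return len(self.planted_ids) / self.n if self.n else 0.0


def generate_sti_db(spec: PlantSpec, seed: int) -> Tuple[STIDatabase, GroundTruth]:
    """Generate a planted-pattern database, fully reproducible from the seed."""
    rng = np.random.default_rng(seed)
    transactions = []
    planted: List[str] = []
    for i in range(spec.n):
        txn_id = f"e{i:04d}"
        stis: List[STI] = []
        if rng.random() < spec.rate:
            shift = rng.uniform(*spec.shift_range)
            stis.extend(s.shifted(shift) for s in spec.template)
            planted.append(txn_id)
        if spec.noise_symbols:
            for _ in range(rng.poisson(spec.noise_mean)):
                symbol = spec.noise_symbols[rng.integers(len(spec.noise_symbols))]
                start = rng.uniform(*spec.noise_start_range)
                stis.append(STI(symbol, start, start + rng.uniform(*spec.noise_duration_range)))
        transactions.append(Transaction(txn_id, tuple(stis)))
    alphabet = frozenset(s.symbol for s in spec.template) | frozenset(spec.noise_symbols)
    db = STIDatabase(transactions, alphabet)
    return db, GroundTruth(spec.tirp, tuple(planted), spec.n)


def default_plant_spec(**overrides) -> PlantSpec:
    """The standard study conditions used across the tests.

    A 3-STI clinical template (low fluids overlapping low appetite, both
    before a fall event) planted in 60% of 200 transactions, with sparse
    disjoint background noise; gaps stay well inside a max_gap of 20
    time units.
    """
    defaults = dict(
        template=(
            STI("Fluids.Low", 0.0, 4.0),
            STI("Appetite.Low", 2.0, 8.0),
            STI("Fall.Event", 10.0, 10.0),
        ),
        rate=0.6,
        n=200,
        noise_mean=3.0,
        noise_symbols=(
            "Exercise.High",
            "Sleep.Long",
            "Coffee.High",
            "Mobility.High",
            "Social.High",
            "Meals.Regular",
        ),
        max_gap=20.0,
    )
    defaults.update(overrides)
    return PlantSpec(**defaults)


# ---------------------------------------------------------------------------
# The canonical toy tree


def _node(
    id: str,
    symbols: Sequence[str],
    rels: str,
    vs: int,
    mhs: float,
    mmd: float,
    parent: Optional[str],
    db_size: int = 100,
) -> TIRPNode:
    return TIRPNode(
        id=id,
        tirp=TIRP(tuple(symbols), tuple(_REL[c] for c in rels)),
        metrics=TIRPMetrics(vs, vs / db_size, mhs, mmd, len(symbols)),
        parent=parent,
    )


def fig1_fixture() -> EnumerationTree:
    """A fixed 18-node toy enumeration tree for worked-example assertions.

    Symbols (abbreviations used below): F = Fall.Event, L = Fluids.Low,
    P = Physical.Decreasing, H = Happiness.Decreasing,
    A = Appetite.Decreasing.  The named structure:

    * P7  = <L b F> — the pattern the exploration walkthroughs focus on;
    * its forward extensions are exactly P12 = <L b F b A>,
      P13 = <L b F b H> and P18 = <P b L b F b A>;
    * its backward extensions are exactly P16 = <P b L b F> and P18;
    * P17 = <H o F b A b P> supplies the earlier-STI row with relation
      "overlaps" and size label 1/4 for a session centred on F;
    * P15 = <H b L b A b F> contains L and F non-consecutively, so it
      matches a positional (first/intermediate/last) query but never a
      consecutive-sequence lookup.

    The remaining nodes are fixed fillers giving every named node its
    prefix chain.  Metrics are synthetic, anti-monotone in VS against a
    notional 100-transaction database.
    """
    F, L, P, H, A = (
        "Fall.Event",
        "Fluids.Low",
        "Physical.Decreasing",
        "Happiness.Decreasing",
        "Appetite.Decreasing",
    )
    tree = EnumerationTree(
        alphabet=frozenset((F, L, P, H, A)), config={"fixture": "fig1"}
    )
    spec = [
        ("P1", (F,), "", 70, 1.40, 0.0, None),
        ("P2", (L,), "", 65, 1.80, 6.0, None),
        ("P3", (P,), "", 60, 1.50, 9.0, None),
        ("P4", (H,), "", 55, 1.30, 7.0, None),
        ("P5", (A,), "", 50, 1.20, 5.0, None),
        ("P6", (F, P), "b", 30, 1.10, 14.0, "P1"),
        ("P7", (L, F), "b", 40, 1.60, 12.0, "P2"),
        ("P8", (P, L), "b", 35, 1.25, 16.0, "P3"),
        ("P9", (H, F), "o", 28, 1.15, 11.0, "P4"),
        ("P10", (H, L), "b", 26, 1.20, 13.0, "P4"),
        ("P11", (H, F, A), "obb", 22, 1.10, 18.0, "P9"),
        ("P12", (L, F, A), "bbb", 24, 1.30, 19.0, "P7"),
        ("P13", (L, F, H), "bbb", 21, 2.08, 13.29, "P7"),
        ("P14", (H, L, A), "bbb", 20, 1.05, 17.0, "P10"),
        ("P16", (P, L, F), "bbb", 25, 1.20, 21.0, "P8"),
        ("P15", (H, L, A, F), "bbbbbb", 17, 1.00, 26.0, "P14"),
        ("P17", (H, F, A, P), "obbbbb", 15, 1.00, 24.0, "P11"),
        ("P18", (P, L, F, A), "bbbbbb", 16, 1.00, 28.0, "P16"),
    ]
    for id, symbols, rels, vs, mhs, mmd, parent in spec:
        tree.add_node(_node(id, symbols, rels, vs, mhs, mmd, parent))
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Random trees for fuzzing


def random_tree(
    n_symbols: int,
    n_nodes: int,
    max_size: int,
    seed: int,
    db_size: int = 1000,
) -> EnumerationTree:
    """Grow a structurally valid random enumeration tree.

    Level 1 holds all ``n_symbols`` symbols; further nodes are created by
    repeatedly extending a random node of size < max_size with a random
    (symbol, relation column) not already among its children.  VS values
    are anti-monotone by construction.  Output is reproducible from the
    seed.
    """
    if n_nodes < n_symbols:
        raise ValueError("n_nodes must be at least n_symbols (one root per symbol)")
    if max_size < 1:
        raise ValueError("max_size must be at least 1")
    if max_size == 1 and n_nodes > n_symbols:
        raise ValueError("max_size 1 admits only the roots; n_nodes is infeasible")
    rng = np.random.default_rng(seed)
    symbols = [f"S{i:02d}" for i in range(n_symbols)]
    rels = list(TemporalRelation)
    tree = EnumerationTree(alphabet=frozenset(symbols), config={"synthetic": True, "seed": seed})

    def metrics(vs: int, size: int) -> TIRPMetrics:
        return TIRPMetrics(
            vs=vs,
            relative_vs=vs / db_size,
            mhs=round(1.0 + 2.0 * float(rng.random()), 3),
            mmd=round(50.0 * float(rng.random()), 3),
            size=size,
        )

    count = 0
    growable: List[str] = []
    for sym in symbols:
        count += 1
        node = TIRPNode(
            id=f"T{count}", tirp=TIRP((sym,)), metrics=metrics(int(rng.integers(200, db_size + 1)), 1)
        )
        tree.add_node(node)
        if max_size > 1:
            growable.append(node.id)

    while count < n_nodes:
        if not growable:
            raise ValueError("tree growth saturated before reaching n_nodes")
        parent = tree[growable[int(rng.integers(len(growable)))]]
        existing = {
            (
                tree[c].tirp.symbols[-1],
                tree[c].tirp.relations[len(parent.tirp.relations) :],
            )
            for c in parent.children
        }
        child_key = None
        for _ in range(30):
            sym = symbols[int(rng.integers(n_symbols))]
            column = tuple(rels[int(rng.integers(7))] for _ in range(parent.size))
            if (sym, column) not in existing:
                child_key = (sym, column)
                break
        if child_key is None:
            if len(existing) >= n_symbols * 7 ** parent.size:
                growable.remove(parent.id)
            continue
        count += 1
        assert parent.metrics is not None
        child = TIRPNode(
            id=f"T{count}",
            tirp=parent.tirp.extend(*child_key),
            metrics=metrics(int(rng.integers(1, parent.metrics.vs + 1)), parent.size + 1),
            parent=parent.id,
        )
        tree.add_node(child)
        if child.size < max_size:
            growable.append(child.id)
    return tree
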