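"""Correctness-first levelwise TIRP miner.

Discovers every frequent TIRP of an STI database and arranges them in
the enumeration tree: level 1 holds the frequent single symbols, and a
size-k node's children are its single-STI forward extensions.  Candidate
generation is instance-driven: for every supporting instance of a node
and every STI lexicographically after the instance's last STI, the new
relation column is read off the actual intervals with
:func:`~tirpscope.core.allen_relation`, candidates are grouped by
(symbol, relation column), and groups whose distinct-transaction count
reaches the minimum vertical support become children.  This trades the
speed of transitivity-table miners (KarmaLego and its successors) for
straightforward provable correctness against exhaustive enumeration.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .core import (
    STI,
    EnumerationTree,
    STIDatabase,
    TIRP,
    TIRPInstance,
    TIRPMetrics,
    TIRPNode,
    TemporalRelation,
    Transaction,
    UNRELATED,
    allen_relation,
)

logger = logging.getLogger(__name__)


@dataclass
class MiningConfig:
    """Mining parameters.

    min_vs: minimum vertical support, either an absolute transaction count
    (int >= 1) or a fraction of the database (float in (0, 1]); a fraction
    is converted once with ceiling at the start of mining.
    max_gap: maximal time between two STIs for BEFORE to hold.
    epsilon: timestamp-equality tolerance for relation classification.
    max_size: optional cap on pattern size (Lmax).
    """

    min_vs: float = 0.2
    max_gap: float = math.inf
    epsilon: float = 0.0
    max_size: Optional[int] = None

    def __post_init__(self) -> None:
        if isinstance(self.min_vs, bool) or self.min_vs <= 0:
            raise ValueError("min_vs must be a positive count or fraction")
        if isinstance(self.min_vs, float) and self.min_vs > 1 and not self.min_vs.is_integer():
            raise ValueError("fractional min_vs must lie in (0, 1]")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.max_size is not None and self.max_size < 1:
            raise ValueError("max_size must be at least 1")

    def resolve_min_vs(self, n_transactions: int) -> int:
        """Absolute support threshold for a database of the given size."""
        if isinstance(self.min_vs, float) and self.min_vs <= 1:
            return max(1, math.ceil(self.min_vs * n_transactions))
        return int(self.min_vs)

    def as_dict(self) -> dict:
        return {
            "min_vs": self.min_vs,
            "max_gap": None if math.isinf(self.max_gap) else self.max_gap,
            "epsilon": self.epsilon,
            "max_size": self.max_size,
        }


def find_instances(
    t: TIRP,
    txn: Transaction,
    epsilon: float = 0.0,
    max_gap: float = math.inf,
) -> List[TIRPInstance]:
    """All instances of ``t`` in a transaction, in lexicographic position order.

    Enumerates the ordered k-subsets of the transaction's sorted STIs
    whose symbols and pairwise relations match ``t``; the result length
    is the pattern's horizontal support in this transaction.
    """
    stis = txn.stis
    out: List[TIRPInstance] = []

    def grow(prefix: Tuple[int, ...]) -> None:
        depth = len(prefix)
        if depth == t.size:
            out.append(
                TIRPInstance(txn.id, tuple(stis[p] for p in prefix), prefix)
            )
            return
        lo = prefix[-1] + 1 if prefix else 0
        want = t.symbols[depth]
        for idx in range(lo, len(stis)):
            cand = stis[idx]
            if cand.symbol != want:
                continue
            ok = True
            for row, p in enumerate(prefix, start=1):
                rel = allen_relation(stis[p], cand, epsilon, max_gap)
                if rel is UNRELATED or rel != t.relation(row, depth + 1):
                    ok = False
                    break
            if ok:
                grow(prefix + (idx,))

    grow(())
    return out


def _metrics(
    tirp: TIRP,
    instances: Mapping[str, Sequence[TIRPInstance]],
    n_transactions: int,
) -> TIRPMetrics:
    vs = len(instances)
    if vs == 0:
        raise ValueError("metrics are undefined for an unsupported pattern")
    hs_values = []
    md_values = []
    for txn_insts in instances.values():
        hs_values.append(len(txn_insts))
        md_values.append(sum(inst.duration for inst in txn_insts) / len(txn_insts))
    return TIRPMetrics(
        vs=vs,
        relative_vs=vs / n_transactions if n_transactions else 0.0,
        mhs=sum(hs_values) / vs,
        mmd=sum(md_values) / vs,
        size=tirp.size,
    )


def compute_metrics(
    node: TIRPNode,
    db: STIDatabase,
    epsilon: float = 0.0,
    max_gap: float = math.inf,
) -> TIRPMetrics:
    """(Re)compute a node's metrics against a database.

    VS counts distinct supporting transactions; per supporting transaction
    HS is the instance count and MD the mean instance span (max end minus
    min start); MHS and MMD average those per-transaction values with
    equal transaction weights.  Uses the node's stored instances when
    present, otherwise re-enumerates them.
    """
    if node.instances is not None:
        instances: Mapping[str, Sequence[TIRPInstance]] = node.instances
    else:
        instances = {}
        for txn in db:
            found = find_instances(node.tirp, txn, epsilon, max_gap)
            if found:
                instances[txn.id] = tuple(found)
    return _metrics(node.tirp, instances, len(db))


def mine_tree(
    db: STIDatabase,
    cfg: MiningConfig,
    keep_instances: bool = True,
) -> EnumerationTree:
    """Mine all frequent TIRPs and build the enumeration tree.

    Deterministic: identical input and config give an identical tree
    (node ids, ordering and metrics).  Children of a node are ordered by
    (extending symbol, relation-column codes).
    """
    min_vs = cfg.resolve_min_vs(len(db))
    tree = EnumerationTree(alphabet=db.alphabet, config={**cfg.as_dict(), "resolved_min_vs": min_vs})
    if min_vs > len(db):
        logger.warning(
            "min_vs (%d) exceeds database size (%d); tree is empty", min_vs, len(db)
        )
        return tree

    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"N{counter}"

    # Level 1: frequent single symbols.
    by_symbol: Dict[str, Dict[str, List[TIRPInstance]]] = {}
    for txn in db:
        for idx, sti in enumerate(txn.stis):
            by_symbol.setdefault(sti.symbol, {}).setdefault(txn.id, []).append(
                TIRPInstance(txn.id, (sti,), (idx,))
            )
    queue: deque = deque()
    for symbol in sorted(by_symbol):
        instances = by_symbol[symbol]
        if len(instances) < min_vs:
            continue
        tirp = TIRP((symbol,))
        inst_map = {tid: tuple(v) for tid, v in instances.items()}
        node = TIRPNode(
            id=next_id(),
            tirp=tirp,
            metrics=_metrics(tirp, inst_map, len(db)),
            supporting=tuple(sorted(inst_map)),
            instances=inst_map,
        )
        tree.add_node(node)
        queue.append(node)

    # Levelwise extension.
    txn_by_id = {txn.id: txn for txn in db}
    while queue:
        node = queue.popleft()
        if cfg.max_size is not None and node.size >= cfg.max_size:
            continue
        # candidates[(symbol, column)][txn_id] -> extended position tuples
        candidates: Dict[
            Tuple[str, Tuple[TemporalRelation, ...]],
            Dict[str, List[Tuple[int, ...]]],
        ] = {}
        assert node.instances is not None
        for txn_id, insts in node.instances.items():
            stis = txn_by_id[txn_id].stis
            for inst in insts:
                assert inst.positions is not None
                last = inst.positions[-1]
                for idx in range(last + 1, len(stis)):
                    ext = stis[idx]
                    column = []
                    for p in inst.positions:
                        rel = allen_relation(stis[p], ext, cfg.epsilon, cfg.max_gap)
                        if rel is UNRELATED:
                            column = None
                            break
                        column.append(rel)
                    if column is None:
                        continue
                    key = (ext.symbol, tuple(column))
                    candidates.setdefault(key, {}).setdefault(txn_id, []).append(
                        inst.positions + (idx,)
                    )
        for key in sorted(
            candidates, key=lambda k: (k[0], tuple(r.value for r in k[1]))
        ):
            supp = candidates[key]
            if len(supp) < min_vs:
                continue
            symbol, column = key
            child_tirp = node.tirp.extend(symbol, column)
            inst_map = {
                tid: tuple(
                    TIRPInstance(
                        tid, tuple(txn_by_id[tid].stis[p] for p in positions), positions
                    )
                    for positions in pos_list
                )
                for tid, pos_list in supp.items()
            }
            child = TIRPNode(
                id=next_id(),
                tirp=child_tirp,
                metrics=_metrics(child_tirp, inst_map, len(db)),
                supporting=tuple(sorted(inst_map)),
                instances=inst_map,
                parent=node.id,
            )
            tree.add_node(child)
            queue.append(child)
        if not keep_instances:
            node.instances = None
    if not keep_instances:
        for node in tree:
            node.instances = None
    return tree
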