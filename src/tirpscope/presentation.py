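"""Plot-ready payloads for the three visual elements.

All functions emit numbers, not charts: a renderer (table, matplotlib,
a web front end) decides the actual drawing.  The timeline shows a
TIRP's "mean presentation": each STI's mean start/end offsets relative
to the pattern's earliest start, averaged per transaction and then
across supporting transactions — the same two-level averaging as MMD.
Bubble points place each extension row at its TIRP's metric values, and
the demographic breakdown gives categorical proportions over the
supporting transactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .core import STIDatabase, TIRPInstance, TIRPNode
from .index import ExtensionRow
from .mining import find_instances

BUBBLE_METRICS = ("relative_vs", "mhs", "mmd", "size")


@dataclass(frozen=True)
class TimelineBar:
    position: int  # 1-based STI position in the TIRP
    symbol: str
    mean_start: float  # offset from the pattern's earliest start, time units
    mean_end: float
    role: str = "other"  # center | earlier | later | other


@dataclass(frozen=True)
class BubblePoint:
    x: float
    y: float
    color_value: float  # raw metric; rendering maps it monotonically to darkness
    label: str


def _instances_by_txn(
    node: TIRPNode,
    db: STIDatabase,
    epsilon: float,
    max_gap: float,
) -> Mapping[str, Sequence[TIRPInstance]]:
    if node.instances is not None:
        return node.instances
    out = {}
    for txn in db:
        found = find_instances(node.tirp, txn, epsilon, max_gap)
        if found:
            out[txn.id] = tuple(found)
    return out


def timeline_layout(
    node: TIRPNode,
    db: STIDatabase,
    epsilon: float = 0.0,
    max_gap: float = math.inf,
    roles: Optional[Dict[int, str]] = None,
) -> List[TimelineBar]:
    """Mean timeline bars of a TIRP, one per STI position.

    Per instance, each STI's start/end is offset by the instance's
    earliest start; offsets are averaged within each supporting
    transaction, then across transactions.  ``roles`` optionally tags
    positions (e.g. {2: "center"}).  Raises if the pattern has no
    recoverable instances.
    """
    instances = _instances_by_txn(node, db, epsilon, max_gap)
    if not instances:
        raise ValueError(
            f"timeline layout undefined: no instances of node {node.id!r}"
        )
    k = node.tirp.size
    roles = roles or {}
    per_txn_means: List[List[Tuple[float, float]]] = []
    for insts in instances.values():
        sums = [[0.0, 0.0] for _ in range(k)]
        for inst in insts:
            base = inst.earliest_start
            for pos, sti in enumerate(inst.stis):
                sums[pos][0] += sti.start - base
                sums[pos][1] += sti.end - base
        per_txn_means.append([(s / len(insts), e / len(insts)) for s, e in sums])
    n_txn = len(per_txn_means)
    bars = []
    for pos in range(k):
        mean_start = sum(m[pos][0] for m in per_txn_means) / n_txn
        mean_end = sum(m[pos][1] for m in per_txn_means) / n_txn
        bars.append(
            TimelineBar(
                position=pos + 1,
                symbol=node.tirp.symbols[pos],
                mean_start=mean_start,
                mean_end=mean_end,
                role=roles.get(pos + 1, "other"),
            )
        )
    return bars


def bubble_points(
    rows: Sequence[ExtensionRow],
    x_metric: str = "relative_vs",
    y_metric: str = "mhs",
    color_metric: str = "mmd",
) -> List[BubblePoint]:
    """One bubble per panel row, placed at its TIRP's metric values.

    Metrics are relative_vs (on the [0, 1] scale), mhs, mmd or size; the
    x and y axes must differ and are freely swappable.  The colour value
    is the raw metric: renderers must map it monotonically (higher value,
    darker bubble).
    """
    for name in (x_metric, y_metric, color_metric):
        if name not in BUBBLE_METRICS:
            raise ValueError(
                f"unknown bubble metric {name!r}; choose from {BUBBLE_METRICS}"
            )
    if x_metric == y_metric:
        raise ValueError("x and y metrics must differ")
    return [
        BubblePoint(
            x=row.metrics.value(x_metric),
            y=row.metrics.value(y_metric),
            color_value=row.metrics.value(color_metric),
            label=f"{row.symbol} ({row.node_id})",
        )
        for row in rows
    ]


def demographic_breakdown(
    node: TIRPNode,
    db: STIDatabase,
    attribute: str,
) -> Dict[str, float]:
    """Proportions of an attribute's values over the supporting transactions.

    Missing values are pooled under ``"unknown"``; proportions sum to 1.
    Raises if the attribute is absent from every transaction of the
    database.
    """
    if not any(attribute in txn.attributes for txn in db):
        raise ValueError(f"attribute {attribute!r} is absent from all transactions")
    counts: Dict[str, int] = {}
    total = 0
    for txn in db:
        if txn.id not in node.supporting:
            continue
        value = txn.attributes.get(attribute, "unknown")
        counts[value] = counts.get(value, 0) + 1
        total += 1
    if total == 0:
        raise ValueError(f"node {node.id!r} has no supporting transactions in this database")
    return {value: count / total for value, count in sorted(counts.items())}
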