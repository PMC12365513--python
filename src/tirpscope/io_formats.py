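"""Readers and writers for the artifact formats.

CSV (RFC 4180) carries raw time series, STI databases and static
attributes; JSON carries enumeration trees, pair indices and chart
payloads.  Writers are canonical (sorted keys, floats at 6 significant
digits, stable node order), so write(read(x)) round-trips byte-identically
for canonicalised documents.  Readers reject malformed input with
line-precise errors instead of coercing it.
"""

from __future__ import annotations

import json
import math
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .abstraction import RawSeries
from .core import (
    STI,
    EnumerationTree,
    STIDatabase,
    TIRP,
    TIRPMetrics,
    TIRPNode,
    TemporalRelation,
    Transaction,
)
from .index import PairIndex

TREE_FORMAT_VERSION = 1


class FormatError(ValueError):
    """Malformed input file; the message names the offending line or field."""


# ---------------------------------------------------------------------------
# CSV: STI databases and attributes

STI_COLUMNS = ["entity_id", "symbol", "start", "end"]


def read_sti_csv(path, attributes_path=None) -> STIDatabase:
    """Read an STI database from CSV (entity_id, symbol, start, end).

    Times must be numeric with start <= end; rows are grouped per entity
    and sorted lexicographically on load.  An optional attributes CSV
    (entity_id, attribute, value) attaches static properties.
    """
    df = pd.read_csv(path, dtype={"entity_id": str, "symbol": str})
    missing = [c for c in STI_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    per_entity: Dict[str, List[STI]] = {}
    for row_idx, row in enumerate(df.itertuples(index=False)):
        line = row_idx + 2  # header is line 1
        try:
            start = float(row.start)
            end = float(row.end)
        except (TypeError, ValueError):
            raise FormatError(f"{path} line {line}: non-numeric time") from None
        if math.isnan(start) or math.isnan(end):
            raise FormatError(f"{path} line {line}: non-numeric time")
        if start > end:
            raise FormatError(f"{path} line {line}: start {start} > end {end}")
        if not isinstance(row.symbol, str) or not row.symbol.strip():
            raise FormatError(f"{path} line {line}: empty symbol")
        per_entity.setdefault(str(row.entity_id), []).append(
            STI(row.symbol, start, end)
        )
    attributes = read_attributes_csv(attributes_path) if attributes_path else {}
    transactions = [
        Transaction(entity, tuple(stis), dict(attributes.get(entity, {})))
        for entity, stis in sorted(per_entity.items())
    ]
    return STIDatabase(transactions)


def read_attributes_csv(path) -> Dict[str, Dict[str, str]]:
    df = pd.read_csv(path, dtype=str)
    for col in ("entity_id", "attribute", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: Dict[str, Dict[str, str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.entity_id), {})[str(row.attribute)] = str(row.value)
    return out


def write_sti_csv(db: STIDatabase, path) -> None:
    rows = [
        {"entity_id": txn.id, "symbol": s.symbol, "start": s.start, "end": s.end}
        for txn in db
        for s in txn.stis
    ]
    pd.DataFrame(rows, columns=STI_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV: raw time series


def read_timeseries_csv(path) -> List[RawSeries]:
    """Read raw samples (entity_id, variable, timestamp, value), one series
    per (entity, variable), sorted by timestamp; duplicate timestamps within
    a series are rejected."""
    df = pd.read_csv(path, dtype={"entity_id": str, "variable": str})
    for col in ("entity_id", "variable", "timestamp", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    series = []
    for (entity, variable), group in df.groupby(["entity_id", "variable"], sort=True):
        group = group.sort_values("timestamp")
        ts = group["timestamp"].tolist()
        if len(set(ts)) != len(ts):
            dup = next(t for i, t in enumerate(ts) if t in ts[:i])
            raise FormatError(
                f"{path}: duplicate timestamp {dup} in series ({entity}, {variable})"
            )
        series.append(
            RawSeries(
                str(entity),
                str(variable),
                tuple(zip((float(t) for t in ts), (float(v) for v in group["value"]))),
            )
        )
    return series


# ---------------------------------------------------------------------------
# JSON: enumeration trees


def _round6(x):
    """Round floats to 6 significant digits, recursively; idempotent."""
    if isinstance(x, bool):
        return x
    if isinstance(x, float):
        if math.isinf(x) or math.isnan(x):
            raise FormatError("non-finite float cannot be serialised")
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    return x


def canonical_json(obj) -> str:
    return json.dumps(_round6(obj), sort_keys=True, separators=(",", ":")) + "\n"


def tree_to_document(tree: EnumerationTree) -> dict:
    nodes = []
    for node in tree:
        if node.metrics is None:
            raise FormatError(f"node {node.id!r} has no metrics; cannot serialise")
        nodes.append(
            {
                "id": node.id,
                "parent": node.parent,
                "symbols": list(node.tirp.symbols),
                "relations": node.tirp.relation_string,
                "vs": node.metrics.vs,
                "relative_vs": node.metrics.relative_vs,
                "mhs": node.metrics.mhs,
                "mmd": node.metrics.mmd,
                "supporting": list(node.supporting),
            }
        )
    return {
        "format_version": TREE_FORMAT_VERSION,
        "config": tree.config,
        "alphabet": sorted(tree.alphabet),
        "nodes": nodes,
    }


def document_to_tree(doc: dict, source: str = "<tree>") -> EnumerationTree:
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise FormatError(f"{source}: not a tree document")
    version = doc.get("format_version")
    if version != TREE_FORMAT_VERSION:
        raise FormatError(f"{source}: unsupported format_version {version!r}")
    tree = EnumerationTree(
        alphabet=frozenset(doc.get("alphabet", [])), config=doc.get("config", {})
    )
    for i, spec in enumerate(doc["nodes"]):
        where = f"{source}: nodes[{i}]"
        for field_name in ("id", "symbols", "relations", "vs", "relative_vs", "mhs", "mmd"):
            if field_name not in spec:
                raise FormatError(f"{where}: missing field {field_name!r}")
        symbols = tuple(spec["symbols"])
        k = len(symbols)
        rel_string = spec["relations"]
        if len(rel_string) != k * (k - 1) // 2:
            raise FormatError(
                f"{where}: relation string length {len(rel_string)} != {k * (k - 1) // 2}"
            )
        try:
            relations = tuple(TemporalRelation.from_code(c) for c in rel_string)
        except ValueError as exc:
            raise FormatError(f"{where}: {exc}") from None
        parent = spec.get("parent")
        if parent is not None and parent not in tree:
            raise FormatError(f"{where}: parent {parent!r} does not precede node")
        metrics = TIRPMetrics(
            vs=int(spec["vs"]),
            relative_vs=float(spec["relative_vs"]),
            mhs=float(spec["mhs"]),
            mmd=float(spec["mmd"]),
            size=k,
        )
        try:
            tree.add_node(
                TIRPNode(
                    id=spec["id"],
                    tirp=TIRP(symbols, relations),
                    metrics=metrics,
                    supporting=tuple(spec.get("supporting", [])),
                    parent=parent,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{where}: {exc}") from None
    return tree


def write_tree(tree: EnumerationTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(canonical_json(tree_to_document(tree)))


def read_tree(path) -> EnumerationTree:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from None
    return document_to_tree(doc, source=str(path))


# ---------------------------------------------------------------------------
# JSON: pair indices


def indices_to_document(forward: PairIndex, backward: PairIndex) -> dict:
    def dump(index: PairIndex) -> dict:
        return {
            k1: {
                k2: [
                    {"node": e.node_id, "position": e.position, "relation": e.relation.value}
                    for e in entries
                ]
                for k2, entries in sorted(inner.items())
            }
            for k1, inner in sorted(index.buckets.items())
        }

    return {
        "format_version": TREE_FORMAT_VERSION,
        "forward": dump(forward),
        "backward": dump(backward),
    }


def write_indices(forward: PairIndex, backward: PairIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(canonical_json(indices_to_document(forward, backward)))
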