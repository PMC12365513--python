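"""Temporal abstraction: raw time-point series -> symbolic time intervals.

Two per-variable methods are supported.  *State* abstraction classifies
each sample value into a labelled bin using expert cutoffs or equal-width
discretisation (EWD).  *Gradient* abstraction classifies each
inter-sample segment by the sign of its slope (Increasing / Stable /
Decreasing against a stability threshold theta).  Adjacent elements with
the same label are then concatenated into STIs, optionally breaking a
run when the sampling gap exceeds ``max_sample_gap`` (useful for
irregularly logged data such as care-home activity records).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import STI, STIDatabase, Transaction

GRADIENT_LABELS = ("Increasing", "Stable", "Decreasing")


@dataclass
class RawSeries:
    """One variable's time-point samples for one entity, strictly increasing in time."""

    entity_id: str
    variable: str
    samples: Tuple[Tuple[float, float], ...]  # (timestamp, value)

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        for (t0, _), (t1, _) in zip(self.samples, self.samples[1:]):
            if t1 <= t0:
                raise ValueError(
                    f"series ({self.entity_id}, {self.variable}): timestamps must "
                    f"be strictly increasing ({t0} then {t1})"
                )

    @property
    def timestamps(self) -> List[float]:
        return [t for t, _ in self.samples]

    @property
    def values(self) -> List[float]:
        return [v for _, v in self.samples]


@dataclass
class VariableConfig:
    """How to abstract one variable.

    method: "state" or "gradient".
    cutoffs/labels: state bins; len(labels) == len(cutoffs) + 1.  Bins are
    left-closed/right-open with the top bin right-closed, so a value equal
    to a cutoff falls into the higher bin.
    theta: gradient stability threshold (|slope| <= theta is Stable).
    """

    method: str = "state"
    cutoffs: Tuple[float, ...] = ()
    labels: Tuple[str, ...] = ()
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("state", "gradient"):
            raise ValueError(f"unknown abstraction method {self.method!r}")
        if any(a >= b for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be strictly ascending")
        if self.method == "state" and self.labels and len(self.labels) != len(self.cutoffs) + 1:
            raise ValueError("state abstraction needs len(labels) == len(cutoffs) + 1")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


@dataclass
class AbstractionConfig:
    """Per-variable configs plus the run-breaking rule.

    max_sample_gap: a run of identical labels breaks when the time step to
    the next element exceeds this (default: no breaks).
    extend_to_next: if True, a state sample's interval is extended to the
    next sample's timestamp instead of ending at its own (off by default:
    we do not invent unobserved duration).
    """

    variables: Dict[str, VariableConfig] = field(default_factory=dict)
    default: VariableConfig = field(default_factory=VariableConfig)
    max_sample_gap: float = math.inf
    extend_to_next: bool = False

    def for_variable(self, name: str) -> VariableConfig:
        return self.variables.get(name, self.default)


def ewd_cutoffs(values: Sequence[float], n_bins: int) -> List[float]:
    """Equal-width discretisation: n_bins - 1 cutoffs evenly spaced over [min, max]."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    lo, hi = min(values), max(values)
    if lo == hi:
        raise ValueError("cannot derive EWD cutoffs from a constant series")
    width = (hi - lo) / n_bins
    return [lo + i * width for i in range(1, n_bins)]


def label_states(
    series: RawSeries,
    cutoffs: Sequence[float],
    labels: Sequence[str],
) -> List[Tuple[str, float, float]]:
    """Label every sample; returns (symbol, start, end) with start == end == timestamp.

    A value v gets bin i such that cutoffs[i-1] <= v < cutoffs[i]; values at
    or above the last cutoff get the top label.  Symbols are
    "Variable.Label".
    """
    if len(labels) != len(cutoffs) + 1:
        raise ValueError("need len(labels) == len(cutoffs) + 1")
    out = []
    for t, v in series.samples:
        i = sum(1 for c in cutoffs if v >= c)
        out.append((f"{series.variable}.{labels[i]}", t, t))
    return out


def label_gradients(
    series: RawSeries,
    theta: float = 0.0,
) -> List[Tuple[str, float, float]]:
    """Label every inter-sample segment by its slope sign.

    Slope above +theta is Increasing, below -theta Decreasing, otherwise
    Stable; the segment spans [t_i, t_{i+1}].  Requires >= 2 samples.
    """
    if len(series.samples) < 2:
        raise ValueError(
            f"series ({series.entity_id}, {series.variable}): gradient "
            "abstraction needs at least two samples"
        )
    out = []
    for (t0, v0), (t1, v1) in zip(series.samples, series.samples[1:]):
        slope = (v1 - v0) / (t1 - t0)
        if slope > theta:
            label = "Increasing"
        elif slope < -theta:
            label = "Decreasing"
        else:
            label = "Stable"
        out.append((f"{series.variable}.{label}", t0, t1))
    return out


def runs_to_stis(
    labeled: Sequence[Tuple[str, float, float]],
    max_sample_gap: float = math.inf,
) -> List[STI]:
    """Concatenate maximal runs of identical symbols into STIs.

    A run breaks when the next element starts more than ``max_sample_gap``
    after the current one ends.  A singleton run of a point sample yields
    a zero-duration STI.
    """
    stis: List[STI] = []
    run: Optional[Tuple[str, float, float]] = None
    for symbol, start, end in labeled:
        if run is not None and symbol == run[0] and start - run[2] <= max_sample_gap:
            run = (run[0], run[1], end)
        else:
            if run is not None:
                stis.append(STI(*run))
            run = (symbol, start, end)
    if run is not None:
        stis.append(STI(*run))
    return stis


def abstract_series(series: RawSeries, config: AbstractionConfig) -> List[STI]:
    """Abstract one series end-to-end: label, optionally extend, merge runs."""
    var_cfg = config.for_variable(series.variable)
    if var_cfg.method == "state":
        if not var_cfg.cutoffs:
            raise ValueError(
                f"variable {series.variable!r}: state abstraction needs cutoffs "
                "(expert-given or from ewd_cutoffs)"
            )
        labeled = label_states(series, var_cfg.cutoffs, var_cfg.labels)
        if config.extend_to_next:
            ts = series.timestamps
            labeled = [
                (sym, s, ts[i + 1] if i + 1 < len(ts) else e)
                for i, (sym, s, e) in enumerate(labeled)
            ]
    else:
        labeled = label_gradients(series, var_cfg.theta)
    return runs_to_stis(labeled, config.max_sample_gap)


def abstract_database(
    series_list: Sequence[RawSeries],
    config: AbstractionConfig,
    attributes: Optional[Dict[str, Dict[str, str]]] = None,
) -> STIDatabase:
    """Abstract a collection of per-entity series into an STI database.

    Series of the same entity are merged into one transaction; per-entity
    static attributes (e.g. gender) can be attached.
    """
    per_entity: Dict[str, List[STI]] = {}
    for series in series_list:
        per_entity.setdefault(series.entity_id, []).extend(
            abstract_series(series, config)
        )
    attributes = attributes or {}
    transactions = [
        Transaction(entity, tuple(stis), dict(attributes.get(entity, {})))
        for entity, stis in sorted(per_entity.items())
    ]
    return STIDatabase(transactions)
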