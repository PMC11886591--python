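"""Per-observer diagnostic performance: micro-averaged accuracy,
sensitivity and specificity, observer ranking, and the always-normal
guessing benchmark.

All metrics are micro-averaged: TP/TN/FP/FN counts are pooled over every
finding the observer assessed (explicit or imputed) before dividing, so
observers who read different numbers of studies are each scored on their
own denominator.  A metric whose denominator is empty (e.g. sensitivity
when the observer saw no consensus-abnormal finding) is UNDEFINED — held
as ``None``, rendered as "-" in reports — never coerced to zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Collection, Iterable, Sequence

import pandas as pd

from .consensus import ConsensusTable
from .errors import EmptyInputError, UnknownObserverError, ValueValidationError
from .reading import KEY_COLUMNS, FindingTable

METRIC_NAMES = ("accuracy", "sensitivity", "specificity")

#: A finding filter is either a collection of (study_id, finding_code)
#: pairs or a predicate over such pairs.
FindingFilter = Collection[tuple[str, str]] | Callable[[tuple[str, str]], bool] | None


@dataclasses.dataclass(frozen=True)
class OutcomeCounts:
    """Pooled TP/TN/FP/FN totals for one observer (and optional stratum)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueValidationError("outcome counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclasses.dataclass(frozen=True)
class ObserverMetrics:
    """Accuracy / sensitivity / specificity with their count basis.

    ``sensitivity`` and ``specificity`` are ``None`` when undefined.
    """

    observer_id: str
    counts: OutcomeCounts
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    is_ai: bool = False

    def get(self, metric: str) -> float | None:
        if metric not in METRIC_NAMES:
            raise ValueValidationError(f"unknown metric {metric!r}")
        return getattr(self, metric)


def metrics(counts: OutcomeCounts, observer_id: str = "", *, is_ai: bool = False) -> ObserverMetrics:
    """Compute the three micro-averaged metrics from pooled counts."""
    total = counts.total
    if total == 0:
        raise EmptyInputError(f"observer {observer_id!r} has no scored findings")
    sens = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    spec = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp > 0 else None
    return ObserverMetrics(
        observer_id=observer_id,
        counts=counts,
        accuracy=(counts.tp + counts.tn) / total,
        sensitivity=sens,
        specificity=spec,
        is_ai=is_ai,
    )


def _scored_records(
    table: FindingTable, consensus: ConsensusTable, finding_filter: FindingFilter = None
) -> pd.DataFrame:
    """Observer-level records joined with their finding's consensus."""
    merged = table.records.merge(
        consensus.records[KEY_COLUMNS + ["consensus"]], on=KEY_COLUMNS
    )
    if finding_filter is None:
        return merged
    keys = pd.MultiIndex.from_frame(merged[KEY_COLUMNS])
    if callable(finding_filter):
        mask = [finding_filter(k) for k in keys]
    else:
        mask = keys.isin(set(finding_filter))
    return merged[mask]


def outcome_counts(
    table: FindingTable,
    consensus: ConsensusTable,
    observer_id: str,
    finding_filter: FindingFilter = None,
) -> OutcomeCounts:
    """Pool TP/TN/FP/FN over the findings one observer assessed.

    Only findings with a consensus label contribute; ``finding_filter``
    optionally restricts to a stratum's keys.
    """
    if observer_id not in table.observers:
        raise UnknownObserverError(observer_id)
    scored = _scored_records(table, consensus, finding_filter)
    scored = scored[scored["observer_id"] == observer_id]
    a, c = scored["assessment"], scored["consensus"]
    return OutcomeCounts(
        tp=int(((a == 1) & (c == 1)).sum()),
        tn=int(((a == 0) & (c == 0)).sum()),
        fp=int(((a == 1) & (c == 0)).sum()),
        fn=int(((a == 0) & (c == 1)).sum()),
    )


def observer_metrics(
    table: FindingTable,
    consensus: ConsensusTable,
    observer_id: str,
    finding_filter: FindingFilter = None,
) -> ObserverMetrics:
    counts = outcome_counts(table, consensus, observer_id, finding_filter)
    return metrics(counts, observer_id, is_ai=observer_id == table.ai_observer_id)


def all_observer_metrics(
    table: FindingTable,
    consensus: ConsensusTable,
    finding_filter: FindingFilter = None,
) -> list[ObserverMetrics]:
    """Metrics for every observer with at least one scored finding."""
    out = []
    for obs in table.observers:
        try:
            out.append(observer_metrics(table, consensus, obs, finding_filter))
        except EmptyInputError:
            continue
    return out


@dataclasses.dataclass(frozen=True)
class RankSummary:
    best: ObserverMetrics
    median: ObserverMetrics
    worst: ObserverMetrics


def rank_humans(
    metrics_list: Sequence[ObserverMetrics],
    metric_name: str,
    *,
    median_position: str = "ceil",
) -> RankSummary:
    """Best, median and worst human observer for one metric.

    Observers whose metric is UNDEFINED are excluded from that metric's
    ranking, so best/median/worst may name different observers per metric.
    With the values sorted descending, the median is the element at
    1-based position ``ceil(h/2)`` of the h defined values (the 6th of 11);
    ``median_position="floor"`` selects position ``floor(h/2)`` instead
    when h is even.  AI observers are dropped before ranking.
    """
    if median_position not in ("ceil", "floor"):
        raise ValueValidationError("median_position must be 'ceil' or 'floor'")
    defined = [
        m for m in metrics_list if not m.is_ai and m.get(metric_name) is not None
    ]
    if not defined:
        raise EmptyInputError(f"no human observer has a defined {metric_name}")
    # stable sort, observer_id breaks ties deterministically
    ordered = sorted(defined, key=lambda m: (-m.get(metric_name), m.observer_id))
    h = len(ordered)
    if median_position == "ceil":
        pos = math.ceil(h / 2)
    else:
        pos = max(1, math.floor(h / 2))
    return RankSummary(best=ordered[0], median=ordered[pos - 1], worst=ordered[-1])


def always_normal_benchmark(
    table: FindingTable,
    consensus: ConsensusTable,
    finding_filter: FindingFilter = None,
) -> float:
    """Accuracy of the classifier that guesses normal for every finding.

    Equals the prevalence of consensus-normal among observer-level
    findings, i.e. one minus the abnormal prevalence — the floor any
    observer should beat on an imbalanced sample.
    """
    scored = _scored_records(table, consensus, finding_filter)
    if len(scored) == 0:
        raise EmptyInputError("no scored observer-level findings")
    return float((scored["consensus"] == 0).mean())
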