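"""Consensus ground truth and outcome classification.

Without an external reference standard, the proxy true state of each
finding is the consensus of all observers who assessed it: the finding is
called abnormal when the mean assessment is at least 0.5 (equivalently,
the median observer called it abnormal; exact ties go to abnormal).  The
rule requires at least ``min_observers`` assessments (default 5); findings
below that are excluded and logged rather than force-labelled.

Each observer's assessment of a finding is then one of four outcomes
relative to the consensus: true positive, true negative, false positive,
false negative.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientObserversError, ValueValidationError
from .reading import KEY_COLUMNS, FindingTable

#: Default minimum panel size for a consensus label.
MIN_OBSERVERS = 5

OUTCOME_LABELS = ("TP", "TN", "FP", "FN")


def consensus_label(
    assessments: Sequence[int] | Iterable[int],
    *,
    min_observers: int = MIN_OBSERVERS,
) -> tuple[float, int]:
    """Mean assessment and consensus label of one finding.

    Returns ``(mean, consensus)`` where ``consensus = 1`` iff
    ``mean >= 0.5`` — an exact half/half split counts as abnormal.

    Raises
    ------
    InsufficientObserversError
        If fewer than ``min_observers`` assessments are supplied.
    """
    a = np.asarray(list(assessments))
    if not np.isin(a, (0, 1)).all():
        raise ValueValidationError("assessments must be binary 0/1")
    if a.size < min_observers:
        raise InsufficientObserversError(
            f"consensus needs >= {min_observers} assessments, got {a.size}"
        )
    mean = float(a.mean())
    return mean, int(mean >= 0.5)


def classify_outcome(assessment: int, consensus: int) -> str:
    """Map (observer assessment, consensus) to TP/TN/FP/FN."""
    if assessment not in (0, 1) or consensus not in (0, 1):
        raise ValueValidationError("assessment and consensus must be binary 0/1")
    if consensus == 1:
        return "TP" if assessment == 1 else "FN"
    return "FP" if assessment == 1 else "TN"


@dataclasses.dataclass
class ConsensusTable:
    """Per-finding consensus labels plus the exclusion log.

    ``records`` has one row per unique finding with enough observers:
    ``study_id, finding_code, n_observers, mean_assessment, consensus``.
    ``excluded`` lists the findings dropped by the panel-size gate.
    """

    records: pd.DataFrame
    excluded: pd.DataFrame
    min_observers: int = MIN_OBSERVERS

    @property
    def n_findings(self) -> int:
        return len(self.records)

    @property
    def abnormal_prevalence(self) -> float:
        """Fraction of unique findings with abnormal consensus."""
        return float(self.records["consensus"].mean())

    def write(self, path) -> None:
        self.records.to_csv(path, index=False)


def build_consensus_table(
    table: FindingTable,
    *,
    min_observers: int = MIN_OBSERVERS,
    exclude_ai_from_consensus: bool = False,
) -> ConsensusTable:
    """Consensus label for every unique finding in an imputed table.

    The AI observer participates in the consensus by default, exactly like
    a human reader; ``exclude_ai_from_consensus`` restricts the panel to
    humans (the gate on ``min_observers`` then applies to humans only).
    """
    records = table.records
    if exclude_ai_from_consensus and table.ai_observer_id is not None:
        records = records[records["observer_id"] != table.ai_observer_id]
    grouped = (
        records.groupby(KEY_COLUMNS, sort=True)["assessment"]
        .agg(n_observers="size", mean_assessment="mean")
        .reset_index()
    )
    grouped["n_observers"] = grouped["n_observers"].astype(int)
    keep = grouped["n_observers"] >= min_observers
    ok = grouped[keep].reset_index(drop=True)
    ok["consensus"] = (ok["mean_assessment"] >= 0.5).astype("int8")
    excluded = grouped.loc[~keep, KEY_COLUMNS + ["n_observers"]].reset_index(drop=True)
    return ConsensusTable(records=ok, excluded=excluded, min_observers=min_observers)
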