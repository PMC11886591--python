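"""Per-finding assessment variance and ambiguity stratification.

Inter-observer disagreement on a finding is quantified as the variance of
the n binary assessments around a reference value:

    V = (1/n) * sum_i (a_i - ref)^2

With the default reference — the binarized consensus label — V is simply
the fraction of observers in the minority, so V = 0 exactly when the
panel is unanimous and V = 0.5 at a perfect split.  A mean-reference mode
(population variance about the mean assessment) is available as an
opt-in alternative reading of the statistic.

Non-unanimous findings are split at the median positive variance:
strictly below is LOW ambiguity, strictly above is HIGH, and findings
exactly at the median form an explicit AT_MEDIAN bucket belonging to
neither stratum (which is why the low and high observation counts need
not sum to the non-unanimous total).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusTable
from .errors import EmptyInputError, ValueValidationError
from .reading import KEY_COLUMNS, FindingTable

UNANIMOUS = "UNANIMOUS"
LOW = "LOW"
HIGH = "HIGH"
AT_MEDIAN = "AT_MEDIAN"
STRATUM_LABELS = (UNANIMOUS, LOW, HIGH, AT_MEDIAN)

#: Subsample names used by reports, mapped to the strata they cover.
SUBSAMPLES = {
    "all": (UNANIMOUS, LOW, HIGH, AT_MEDIAN),
    "no_unanimity": (LOW, HIGH, AT_MEDIAN),
    "low": (LOW,),
    "high": (HIGH,),
}

VARIANCE_REFERENCES = ("consensus", "mean")


def assessment_variance(
    assessments: Sequence[int] | Iterable[int],
    reference: str | float = "consensus",
) -> float:
    """Variance of binary assessments around a reference.

    ``reference`` is ``"consensus"`` (binarized majority label, ties
    abnormal — the default), ``"mean"`` (population variance), or an
    explicit numeric value.
    """
    a = np.asarray(list(assessments), dtype=float)
    if a.size == 0:
        raise EmptyInputError("variance of an empty assessment list")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueValidationError("assessments must be binary 0/1")
    if reference == "consensus":
        ref = float(a.mean() >= 0.5)
    elif reference == "mean":
        ref = float(a.mean())
    elif isinstance(reference, (int, float)):
        ref = float(reference)
    else:
        raise ValueValidationError(f"unknown variance reference {reference!r}")
    return float(np.mean((a - ref) ** 2))


def variance_table(
    table: FindingTable,
    consensus: ConsensusTable,
    *,
    reference: str = "consensus",
) -> pd.DataFrame:
    """Per unique finding: ``study_id, finding_code, n_observers, variance``.

    Only findings with a consensus label (panel-size gate passed) appear.
    """
    if reference not in VARIANCE_REFERENCES:
        raise ValueValidationError(f"unknown variance reference {reference!r}")
    merged = table.records.merge(consensus.records, on=KEY_COLUMNS)
    if reference == "consensus":
        merged["_sq"] = (merged["assessment"] - merged["consensus"]) ** 2
        grouped = (
            merged.groupby(KEY_COLUMNS, sort=True)
            .agg(n_observers=("assessment", "size"), variance=("_sq", "mean"))
            .reset_index()
        )
    else:
        grouped = (
            merged.groupby(KEY_COLUMNS, sort=True)["assessment"]
            .agg(n_observers="size", variance=lambda s: s.var(ddof=0))
            .reset_index()
        )
    grouped["n_observers"] = grouped["n_observers"].astype(int)
    grouped["variance"] = grouped["variance"].astype(float)
    return grouped


@dataclasses.dataclass
class StrataTable:
    """Stratum assignment per unique finding plus the split point.

    ``records`` columns: ``study_id, finding_code, variance, n_observers,
    stratum``.  ``median_variance`` is NaN when every finding is
    unanimous (LOW/HIGH are then empty).
    """

    records: pd.DataFrame
    median_variance: float

    def keys(self, *labels: str) -> set[tuple[str, str]]:
        """Finding keys belonging to any of the given stratum labels."""
        for lab in labels:
            if lab not in STRATUM_LABELS:
                raise ValueValidationError(f"unknown stratum {lab!r}")
        mask = self.records["stratum"].isin(labels)
        sub = self.records.loc[mask, KEY_COLUMNS]
        return set(map(tuple, sub.itertuples(index=False)))

    def subsample_keys(self, name: str) -> set[tuple[str, str]] | None:
        """Keys for a named subsample; None for "all" (no filtering)."""
        if name not in SUBSAMPLES:
            raise ValueValidationError(f"unknown subsample {name!r}")
        if name == "all":
            return None
        return self.keys(*SUBSAMPLES[name])

    def counts(self) -> dict[str, int]:
        c = self.records["stratum"].value_counts().to_dict()
        return {lab: int(c.get(lab, 0)) for lab in STRATUM_LABELS}

    def write(self, path) -> None:
        self.records.to_csv(path, index=False)


def stratify(variances: pd.DataFrame, *, median_scope: str = "findings") -> StrataTable:
    """Assign each finding to UNANIMOUS / LOW / HIGH / AT_MEDIAN.

    The median is taken over positive variances only.  ``median_scope``
    chooses its weighting: ``"findings"`` (default) uses one value per
    unique finding; ``"observations"`` repeats each finding's variance by
    its observer count, weighting the median by observation volume.
    """
    if median_scope not in ("findings", "observations"):
        raise ValueValidationError(f"unknown median_scope {median_scope!r}")
    out = variances.copy()
    v = out["variance"].to_numpy(dtype=float)
    positive = v > 0
    if positive.any():
        if median_scope == "findings":
            med = float(np.median(v[positive]))
        else:
            med = float(np.median(np.repeat(v[positive], out.loc[positive, "n_observers"])))
    else:
        med = float("nan")
    stratum = np.full(len(out), UNANIMOUS, dtype=object)
    stratum[positive & (v < med)] = LOW
    stratum[positive & (v > med)] = HIGH
    stratum[positive & (v == med)] = AT_MEDIAN
    out["stratum"] = stratum
    return StrataTable(records=out, median_variance=med)


def distribution_table(
    table: FindingTable,
    consensus: ConsensusTable,
    strata: StrataTable,
) -> pd.DataFrame:
    """Normal/abnormal composition of each subsample, observer-level.

    One column per subsample (all, no unanimity, low, high); rows give
    the percentage of observer-level findings whose consensus is normal
    or abnormal and the total observation count.  Stratum membership of a
    finding applies to every observer-level observation of it.
    """
    merged = table.records.merge(consensus.records, on=KEY_COLUMNS).merge(
        strata.records[KEY_COLUMNS + ["stratum"]], on=KEY_COLUMNS
    )
    cols = {}
    for name, labels in SUBSAMPLES.items():
        sub = merged[merged["stratum"].isin(labels)]
        n = len(sub)
        normal_pct = float((sub["consensus"] == 0).mean() * 100) if n else float("nan")
        cols[name] = {
            "normal_pct": normal_pct,
            "abnormal_pct": 100.0 - normal_pct if n else float("nan"),
            "n_observations": n,
        }
    return pd.DataFrame(cols)
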