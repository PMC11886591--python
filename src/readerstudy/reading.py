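"""Data model and I/O for multi-reader finding assessments.

The central relation is a long-format table with one row per
(study, finding code, observer) assessment.  A *finding* is one codable
radiographic observation within one study; each observer labels it normal
(0) or abnormal (1).  Observers are human radiologists plus, optionally,
one AI system; the reading design records which observer reported on which
study, since reader panels are usually incomplete (each radiologist reads
only a subset of studies).

Reports only state a subset of findings explicitly.  The convention for
silence is *unmentioned means normal*: if some observer raised a finding
for a study and another reader of that same study did not mention it, the
silent reader is taken to have judged it normal.
:func:`impute_unmentioned` materialises those implicit records, flagged
with ``mentioned=False`` so downstream reports can state the imputed
fraction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import (
    DesignViolationError,
    EmptyInputError,
    FormatError,
    ValueValidationError,
)

#: Columns required in a findings CSV (``mentioned`` is optional on input).
FINDINGS_COLUMNS = ("study_id", "finding_code", "observer_id", "assessment")
DESIGN_COLUMNS = ("observer_id", "study_id")
KEY_COLUMNS = ["study_id", "finding_code"]
RECORD_COLUMNS = ["study_id", "finding_code", "observer_id", "assessment", "mentioned"]

_ASSESSMENT_VALUES = {"0": 0, "1": 1, "normal": 0, "abnormal": 1}
_BOOL_VALUES = {"0": False, "1": True, "false": False, "true": True}


def _parse_assessment(series: pd.Series) -> pd.Series:
    cleaned = series.astype(str).str.strip().str.lower()
    bad = ~cleaned.isin(_ASSESSMENT_VALUES)
    if bad.any():
        offending = sorted(cleaned[bad].unique())
        raise ValueValidationError(
            f"assessment values outside {{normal, abnormal, 0, 1}}: {offending}"
        )
    return cleaned.map(_ASSESSMENT_VALUES).astype("int8")


def _parse_bool(series: pd.Series) -> pd.Series:
    cleaned = series.astype(str).str.strip().str.lower()
    bad = ~cleaned.isin(_BOOL_VALUES)
    if bad.any():
        raise ValueValidationError(
            f"mentioned flags must be boolean-like, got {sorted(cleaned[bad].unique())}"
        )
    return cleaned.map(_BOOL_VALUES).astype(bool)


def _canonical_records(records: pd.DataFrame) -> pd.DataFrame:
    out = records.loc[:, RECORD_COLUMNS].copy()
    for col in ("study_id", "finding_code", "observer_id"):
        out[col] = out[col].astype(str)
    out["assessment"] = out["assessment"].astype("int8")
    out["mentioned"] = out["mentioned"].astype(bool)
    return out.sort_values(RECORD_COLUMNS[:3], kind="mergesort").reset_index(drop=True)


def _canonical_design(design: pd.DataFrame) -> pd.DataFrame:
    out = design.loc[:, list(DESIGN_COLUMNS)].copy()
    for col in DESIGN_COLUMNS:
        out[col] = out[col].astype(str)
    return (
        out.drop_duplicates()
        .sort_values(list(DESIGN_COLUMNS), kind="mergesort")
        .reset_index(drop=True)
    )


@dataclasses.dataclass
class FindingTable:
    """Validated container of assessment records plus the reading design.

    Parameters
    ----------
    records
        DataFrame with columns ``study_id, finding_code, observer_id,
        assessment, mentioned``.  ``assessment`` is binary (0 normal,
        1 abnormal); ``mentioned`` is False only for records imputed by the
        unmentioned-means-normal rule, which are necessarily normal.
    design
        DataFrame with columns ``observer_id, study_id``: one row per
        report an observer produced.
    ai_observer_id
        Observer id of the AI system, or None when the panel is all human.
    """

    records: pd.DataFrame
    design: pd.DataFrame
    ai_observer_id: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FINDINGS_COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"findings table lacks columns {missing}")
        records = self.records.copy()
        if "mentioned" not in records.columns:
            records["mentioned"] = True
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise FormatError(f"design table lacks columns {missing}")
        self.records = _canonical_records(records)
        self.design = _canonical_design(self.design)
        self._validate()

    def _validate(self) -> None:
        dup = self.records.duplicated(subset=RECORD_COLUMNS[:3])
        if dup.any():
            first = self.records.loc[dup.idxmax(), RECORD_COLUMNS[:3]].tolist()
            raise DesignViolationError(
                f"duplicate assessment for (study, finding, observer) {tuple(first)}"
            )
        bad = (~self.records["mentioned"]) & (self.records["assessment"] != 0)
        if bad.any():
            raise FormatError("imputed (unmentioned) records must be normal")
        pairs = self.records[["observer_id", "study_id"]].drop_duplicates()
        merged = pairs.merge(self.design, on=list(DESIGN_COLUMNS), how="left", indicator=True)
        outside = merged["_merge"] == "left_only"
        if outside.any():
            row = merged.loc[outside.idxmax()]
            raise DesignViolationError(
                f"observer {row['observer_id']!r} has records for study "
                f"{row['study_id']!r} outside the reading design"
            )
        if self.ai_observer_id is not None:
            self.ai_observer_id = str(self.ai_observer_id)

    # -- convenience views ------------------------------------------------

    @property
    def observers(self) -> list[str]:
        return sorted(self.design["observer_id"].unique())

    @property
    def human_observers(self) -> list[str]:
        return [o for o in self.observers if o != self.ai_observer_id]

    @property
    def studies(self) -> list[str]:
        return sorted(self.design["study_id"].unique())

    def readers_of(self, study_id: str) -> list[str]:
        mask = self.design["study_id"] == str(study_id)
        return sorted(self.design.loc[mask, "observer_id"])

    def study_universe(self, study_id: str) -> list[str]:
        """Finding codes raised by any reader of this study."""
        mask = self.records["study_id"] == str(study_id)
        return sorted(self.records.loc[mask, "finding_code"].unique())

    def equals(self, other: "FindingTable") -> bool:
        return (
            self.records.equals(other.records)
            and self.design.equals(other.design)
            and self.ai_observer_id == other.ai_observer_id
        )


def load_findings(
    path: str | Path,
    design_path: str | Path,
    *,
    registry_path: str | Path | None = None,
    ai_observer_id: str | None = None,
) -> FindingTable:
    """Read findings and design CSVs into a validated :class:`FindingTable`.

    The findings CSV requires the header ``study_id,finding_code,
    observer_id,assessment`` with assessments in {0, 1, normal, abnormal};
    an optional ``mentioned`` column (0/1) marks imputation provenance.
    The design CSV requires ``observer_id,study_id``.  The optional
    registry YAML names the AI observer under the key ``ai_observer_id``.
    """
    fdf = pd.read_csv(path, dtype=str)
    missing = [c for c in FINDINGS_COLUMNS if c not in fdf.columns]
    if missing:
        raise FormatError(f"findings CSV {path} lacks columns {missing}")
    fdf["assessment"] = _parse_assessment(fdf["assessment"])
    if "mentioned" in fdf.columns:
        fdf["mentioned"] = _parse_bool(fdf["mentioned"])
    else:
        fdf["mentioned"] = True

    ddf = pd.read_csv(design_path, dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in ddf.columns]
    if missing:
        raise FormatError(f"design CSV {design_path} lacks columns {missing}")

    if registry_path is not None:
        registry = yaml.safe_load(Path(registry_path).read_text())
        if not isinstance(registry, Mapping):
            raise FormatError(f"observer registry {registry_path} is not a mapping")
        ai_observer_id = registry.get("ai_observer_id", ai_observer_id)

    return FindingTable(records=fdf, design=ddf, ai_observer_id=ai_observer_id)


def write_findings(
    table: FindingTable,
    path: str | Path,
    design_path: str | Path,
    *,
    registry_path: str | Path | None = None,
) -> None:
    """Write a table back to the CSV/YAML external interface.

    Round-trips exactly: ``load_findings(*write_findings(t)) == t``.
    """
    out = table.records.copy()
    out["mentioned"] = out["mentioned"].astype(int)
    out.to_csv(path, index=False)
    table.design.to_csv(design_path, index=False)
    if registry_path is not None:
        Path(registry_path).write_text(
            yaml.safe_dump({"ai_observer_id": table.ai_observer_id})
        )


def impute_unmentioned(table: FindingTable) -> FindingTable:
    """Complete the table under the unmentioned-means-normal rule.

    The finding universe of each study is the union of finding codes raised
    by *any* of its readers.  For every reader of the study and every code
    in the universe without an explicit record, a normal record flagged
    ``mentioned=False`` is added.  Explicit records are untouched, readers
    gain nothing for studies outside their design, and the operation is
    idempotent.
    """
    universe = table.records[KEY_COLUMNS].drop_duplicates()
    full = table.design.merge(universe, on="study_id")
    merged = full.merge(
        table.records,
        on=["study_id", "finding_code", "observer_id"],
        how="left",
    )
    merged["assessment"] = merged["assessment"].fillna(0).astype("int8")
    merged["mentioned"] = merged["mentioned"].astype("boolean").fillna(False).astype(bool)
    return FindingTable(
        records=merged,
        design=table.design,
        ai_observer_id=table.ai_observer_id,
    )


@dataclasses.dataclass(frozen=True)
class DesignSummary:
    """Headline counts of a (typically imputed) finding table."""

    n_studies: int
    n_observers: int
    reports_per_observer: dict[str, int]
    total_observer_findings: int
    n_unique_findings: int
    abnormal_prevalence: float
    imputed_fraction: float

    @property
    def mean_reports_per_observer(self) -> float:
        return sum(self.reports_per_observer.values()) / len(self.reports_per_observer)


def design_summary(table: FindingTable) -> DesignSummary:
    """Counts of studies, observers, reports and observer-level findings."""
    if len(table.records) == 0:
        raise EmptyInputError("cannot summarise an empty finding table")
    reports = table.design.groupby("observer_id").size().to_dict()
    n_records = len(table.records)
    return DesignSummary(
        n_studies=len(table.studies),
        n_observers=len(table.observers),
        reports_per_observer=reports,
        total_observer_findings=n_records,
        n_unique_findings=len(table.records[KEY_COLUMNS].drop_duplicates()),
        abnormal_prevalence=float(table.records["assessment"].mean()),
        imputed_fraction=float((~table.records["mentioned"]).mean()),
    )
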