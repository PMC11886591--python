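"""End-to-end orchestration: imputation, consensus, stratification,
per-observer metric tables with significance stars, and the run log.

The analysis path is fully deterministic: all randomness lives in the
synthetic generator.  Re-running on the bundle's own emitted findings and
design CSVs reproduces the bundle.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import ambiguity, inference, performance
from .consensus import MIN_OBSERVERS, ConsensusTable, build_consensus_table
from .errors import ConfigError, EmptyInputError
from .reading import FindingTable, design_summary, impute_unmentioned, write_findings

#: Subsample order used for the per-observer metric tables.
SUBSAMPLE_ORDER = ("all", "no_unanimity", "low", "high")


@dataclasses.dataclass
class PipelineOptions:
    """Tunable knobs of the analysis path (not of the data)."""

    min_observers: int = MIN_OBSERVERS
    exclude_ai_from_consensus: bool = False
    variance_reference: str = "consensus"
    median_scope: str = "findings"
    alpha: float = 0.05
    median_position: str = "ceil"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.min_observers < 2:
            raise ConfigError("min_observers must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineOptions":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"pipeline config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        raw = {k: v for k, v in raw.items() if k in known}
        raw.update(overrides)
        return cls(**raw)


@dataclasses.dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    table: FindingTable  # imputed
    consensus: ConsensusTable
    strata: ambiguity.StrataTable
    distribution: pd.DataFrame
    metric_tables: dict[str, pd.DataFrame]
    ai_tests: pd.DataFrame
    benchmark_tests: pd.DataFrame
    run_log: dict

    def write(self, outdir: str | Path) -> None:
        """Materialise the bundle as plain CSV/JSON under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_findings(
            self.table,
            out / "findings_imputed.csv",
            out / "design.csv",
            registry_path=out / "observers.yaml",
        )
        self.consensus.write(out / "consensus.csv")
        self.strata.write(out / "strata.csv")
        self.distribution.to_csv(out / "distribution.csv")
        for name, df in self.metric_tables.items():
            rendered = df.copy()
            for col in ("sensitivity", "specificity"):
                rendered[col] = rendered[col].map(
                    lambda v: "-" if pd.isna(v) else f"{v:.6f}"
                )
            rendered.to_csv(out / f"metrics_{name}.csv", index=False)
        self.ai_tests.to_csv(out / "tests_vs_ai.csv", index=False)
        self.benchmark_tests.to_csv(out / "tests_vs_benchmark.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2, sort_keys=True))


def _metric_table(
    table: FindingTable,
    consensus: ConsensusTable,
    keys: set | None,
    subsample: str,
) -> tuple[pd.DataFrame, list[inference.TestResult]]:
    ms = performance.all_observer_metrics(table, consensus, keys)
    if not ms:
        raise EmptyInputError(f"no observer has scored findings in subsample {subsample!r}")
    tests: list[inference.TestResult] = []
    if table.ai_observer_id is not None and any(
        m.observer_id == table.ai_observer_id for m in ms
    ):
        tests = inference.compare_humans_vs_ai(
            ms, table.ai_observer_id, stratum=subsample
        )
    stars = {(t.metric, t.observer_id): t.stars for t in tests}
    rows = []
    for m in ms:
        c = m.counts
        rows.append(
            {
                "observer_id": m.observer_id,
                "is_ai": m.is_ai,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "accuracy_stars": stars.get(("accuracy", m.observer_id), ""),
                "sensitivity_stars": stars.get(("sensitivity", m.observer_id), ""),
                "specificity_stars": stars.get(("specificity", m.observer_id), ""),
                "tp": c.tp,
                "tn": c.tn,
                "fp": c.fp,
                "fn": c.fn,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["accuracy", "observer_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df, tests


def run_pipeline(
    table: FindingTable, options: PipelineOptions | None = None
) -> ReportBundle:
    """Run the full analysis on a (possibly un-imputed) finding table.

    Produces the subsample distribution table, four per-observer metric
    tables (all / no unanimity / low / high ambiguity, sorted by accuracy
    descending) with Bonferroni-starred human-vs-AI comparisons, the
    benchmark comparisons, and a run log recording exclusions, the
    imputed fraction and the AT_MEDIAN count.
    """
    options = options or PipelineOptions()
    table = impute_unmentioned(table)
    summary = design_summary(table)
    consensus = build_consensus_table(
        table,
        min_observers=options.min_observers,
        exclude_ai_from_consensus=options.exclude_ai_from_consensus,
    )
    variances = ambiguity.variance_table(
        table, consensus, reference=options.variance_reference
    )
    strata = ambiguity.stratify(variances, median_scope=options.median_scope)
    distribution = ambiguity.distribution_table(table, consensus, strata)

    metric_tables: dict[str, pd.DataFrame] = {}
    all_tests: list[inference.TestResult] = []
    for subsample in SUBSAMPLE_ORDER:
        keys = strata.subsample_keys(subsample)
        try:
            df, tests = _metric_table(table, consensus, keys, subsample)
        except EmptyInputError:
            df = pd.DataFrame()
            tests = []
        metric_tables[subsample] = df
        all_tests.extend(tests)

    normal_prev = performance.always_normal_benchmark(table, consensus)
    bench = inference.compare_vs_benchmark(
        performance.all_observer_metrics(table, consensus), normal_prev
    )

    stratum_counts = strata.counts()
    run_log = {
        "n_studies": summary.n_studies,
        "n_observers": summary.n_observers,
        "total_observer_findings": summary.total_observer_findings,
        "n_unique_findings": summary.n_unique_findings,
        "imputed_fraction": summary.imputed_fraction,
        "excluded_findings_below_min_observers": int(len(consensus.excluded)),
        "min_observers": options.min_observers,
        "median_variance": None
        if pd.isna(strata.median_variance)
        else strata.median_variance,
        "stratum_counts_unique_findings": stratum_counts,
        "at_median_findings": stratum_counts[ambiguity.AT_MEDIAN],
        "normal_prevalence_observations": normal_prev,
        "benchmark_accuracy": normal_prev,
        "options": dataclasses.asdict(options),
    }
    return ReportBundle(
        table=table,
        consensus=consensus,
        strata=strata,
        distribution=distribution,
        metric_tables=metric_tables,
        ai_tests=inference.results_frame(all_tests),
        benchmark_tests=inference.results_frame(bench),
        run_log=run_log,
    )
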