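"""Proportion tests with Bonferroni correction.

Two comparisons are supported: each human observer against the AI on the
same metric (unpaired pooled two-proportion z-test, each observer's own
numerator and denominator), and any observer against the always-normal
guessing benchmark (one-proportion z-test against the fixed normal
prevalence).  Within one metric in one subsample all human-vs-AI tests
form a single Bonferroni family; observers whose metric is undefined are
skipped and shrink the family.

All tests are two-sided.  A comparison whose pooled proportion is 0 or 1
carries no information (the z statistic is undefined); such tests are
reported with p = 1 and a degenerate flag rather than a bogus statistic.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .errors import (
    DegenerateTestError,
    EmptyInputError,
    UnknownObserverError,
    ValueValidationError,
)
from .performance import METRIC_NAMES, ObserverMetrics

#: Significance-star thresholds on the adjusted p-value.
STAR_THRESHOLDS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))
ALPHA = 0.05


def _check_counts(x: int, n: int, name: str) -> None:
    if n <= 0:
        raise ValueValidationError(f"{name}: trials must be positive")
    if not 0 <= x <= n:
        raise ValueValidationError(f"{name}: successes must lie in [0, n]")


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled
    proportion (x1+x2)/(n1+n2).

    Raises
    ------
    DegenerateTestError
        If the pooled proportion is 0 or 1 (zero pooled variance).
    """
    _check_counts(x1, n1, "sample 1")
    _check_counts(x2, n2, "sample 2")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateTestError("pooled proportion is degenerate (0 or 1)")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return z, float(2 * norm.sf(abs(z)))


def one_proportion_ztest(x: int, n: int, p0: float) -> tuple[float, float]:
    """One-sample z-test of x/n against a fixed proportion p0, two-sided.

    The standard error uses the null proportion: sqrt(p0(1-p0)/n).
    """
    _check_counts(x, n, "sample")
    if not 0 < p0 < 1:
        raise DegenerateTestError("benchmark proportion must lie strictly in (0, 1)")
    z = (x / n - p0) / math.sqrt(p0 * (1 - p0) / n)
    return z, float(2 * norm.sf(abs(z)))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjust p-values: multiply by the family size m, cap at 1."""
    if len(p_values) == 0:
        raise EmptyInputError("no p-values to adjust")
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueValidationError("family size m must be >= number of p-values")
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueValidationError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def significance_stars(p_adj: float) -> str:
    for threshold, mark in STAR_THRESHOLDS:
        if p_adj < threshold:
            return mark
    return ""


@dataclasses.dataclass(frozen=True)
class TestResult:
    """One proportion test inside a Bonferroni family."""

    metric: str
    stratum: str
    observer_id: str
    comparator: str  # AI observer id or "benchmark"
    z: float
    p_raw: float
    p_adj: float
    m: int
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_adj < ALPHA

    @property
    def stars(self) -> str:
        return significance_stars(self.p_adj)


def _proportion_counts(m: ObserverMetrics, metric: str) -> tuple[int, int] | None:
    """(successes, trials) behind one metric, or None when undefined."""
    c = m.counts
    if metric == "accuracy":
        return c.tp + c.tn, c.total
    if metric == "sensitivity":
        return (c.tp, c.tp + c.fn) if c.tp + c.fn > 0 else None
    if metric == "specificity":
        return (c.tn, c.tn + c.fp) if c.tn + c.fp > 0 else None
    raise ValueValidationError(f"unknown metric {metric!r}")


def compare_humans_vs_ai(
    metrics_list: Sequence[ObserverMetrics],
    ai_observer_id: str,
    *,
    stratum: str = "all",
    metric_names: Sequence[str] = METRIC_NAMES,
) -> list[TestResult]:
    """Two-proportion tests of every human against the AI, per metric.

    For each metric, the family consists of the humans whose metric is
    defined; its size m is the Bonferroni multiplier.  A metric undefined
    for the AI yields no tests.  The AI is never compared to itself.
    """
    ai = next((m for m in metrics_list if m.observer_id == ai_observer_id), None)
    if ai is None:
        raise UnknownObserverError(ai_observer_id)
    humans = [m for m in metrics_list if m.observer_id != ai_observer_id]
    results: list[TestResult] = []
    for metric in metric_names:
        ai_counts = _proportion_counts(ai, metric)
        if ai_counts is None:
            continue
        tested = [(h, _proportion_counts(h, metric)) for h in humans]
        tested = [(h, c) for h, c in tested if c is not None]
        m_family = len(tested)
        for h, (x, n) in tested:
            degenerate = False
            try:
                z, p_raw = two_proportion_ztest(x, n, *ai_counts)
            except DegenerateTestError:
                z, p_raw, degenerate = float("nan"), 1.0, True
            results.append(
                TestResult(
                    metric=metric,
                    stratum=stratum,
                    observer_id=h.observer_id,
                    comparator=ai_observer_id,
                    z=z,
                    p_raw=p_raw,
                    p_adj=min(1.0, m_family * p_raw),
                    m=m_family,
                    degenerate=degenerate,
                )
            )
    return results


def compare_vs_benchmark(
    metrics_list: Sequence[ObserverMetrics],
    normal_prevalence: float,
    *,
    stratum: str = "all",
) -> list[TestResult]:
    """One-proportion test of each observer's accuracy against guessing.

    The benchmark p0 is the prevalence of consensus-normal findings — the
    accuracy of always guessing normal — evaluated on each observer's own
    denominator.  All observers (AI included) form one family.
    """
    results: list[TestResult] = []
    tested = [(m, _proportion_counts(m, "accuracy")) for m in metrics_list]
    m_family = len(tested)
    if m_family == 0:
        raise EmptyInputError("no observers to compare against the benchmark")
    for obs, (x, n) in tested:
        degenerate = False
        try:
            z, p_raw = one_proportion_ztest(x, n, normal_prevalence)
        except DegenerateTestError:
            z, p_raw, degenerate = float("nan"), 1.0, True
        results.append(
            TestResult(
                metric="accuracy",
                stratum=stratum,
                observer_id=obs.observer_id,
                comparator="benchmark",
                z=z,
                p_raw=p_raw,
                p_adj=min(1.0, m_family * p_raw),
                m=m_family,
                degenerate=degenerate,
            )
        )
    return results


def results_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    """Flatten test results to the tests CSV layout."""
    rows = [
        {
            "metric": r.metric,
            "stratum": r.stratum,
            "observer_id": r.observer_id,
            "comparator": r.comparator,
            "z": r.z,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "m": r.m,
            "significant": r.significant,
            "stars": r.stars,
            "degenerate": r.degenerate,
        }
        for r in results
    ]
    columns = [
        "metric", "stratum", "observer_id", "comparator", "z",
        "p_raw", "p_adj", "m", "significant", "stars", "degenerate",
    ]
    return pd.DataFrame(rows, columns=columns)
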