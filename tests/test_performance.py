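"""Micro-averaged observer metrics, ranking, and the guessing benchmark."""

import pytest

from readerstudy import (
    EmptyInputError,
    ObserverMetrics,
    OutcomeCounts,
    all_observer_metrics,
    always_normal_benchmark,
    build_consensus_table,
    impute_unmentioned,
    metrics,
    outcome_counts,
    rank_humans,
    stratify,
    variance_table,
)
from conftest import table_from_rows


def _metrics_from_values(values, is_ai=None):
    out = []
    for i, v in enumerate(values):
        out.append(
            ObserverMetrics(
                observer_id=f"R{i + 1}",
                counts=OutcomeCounts(tp=1, tn=1),
                accuracy=v,
                sensitivity=v,
                specificity=v,
                is_ai=bool(is_ai and i in is_ai),
            )
        )
    return out


def test_metric_arithmetic():
    m = metrics(OutcomeCounts(tp=8, tn=80, fp=10, fn=2))
    assert m.accuracy == pytest.approx(0.88)
    assert m.sensitivity == pytest.approx(0.8)
    assert m.specificity == pytest.approx(80 / 90)


def test_undefined_metrics_are_none_not_zero():
    m = metrics(OutcomeCounts(tp=0, tn=50, fp=5, fn=0))
    assert m.sensitivity is None
    assert m.specificity == pytest.approx(50 / 55)

    m2 = metrics(OutcomeCounts(fn=1))
    assert m2.accuracy == 0.0
    assert m2.sensitivity == 0.0
    assert m2.specificity is None

    with pytest.raises(EmptyInputError):
        metrics(OutcomeCounts())


def test_outcome_counts_against_consensus():
    observers = [f"O{i}" for i in range(5)]
    rows = []
    # 10 findings everyone calls normal, 2 everyone calls abnormal
    for k in range(12):
        label = 1 if k < 2 else 0
        rows += [("S1", f"C{k}", o, label) for o in observers]
    # one contrarian observer who always says abnormal
    rows = [r for r in rows if r[2] != "O4"]
    rows += [("S1", f"C{k}", "O4", 1) for k in range(12)]
    table = table_from_rows(rows, [(o, "S1") for o in observers])
    consensus = build_consensus_table(table)

    agree = outcome_counts(table, consensus, "O0")
    assert (agree.tp, agree.tn, agree.fp, agree.fn) == (2, 10, 0, 0)
    contrarian = outcome_counts(table, consensus, "O4")
    assert (contrarian.tp, contrarian.tn, contrarian.fp, contrarian.fn) == (2, 0, 10, 0)


def test_stratum_counts_recombine_to_pooled(default_panel):
    """Counts restricted to disjoint strata sum back to the total."""
    table, _ = default_panel
    imputed = impute_unmentioned(table)
    consensus = build_consensus_table(imputed)
    strata = stratify(variance_table(imputed, consensus))
    for obs in imputed.observers[:4]:
        pooled = outcome_counts(imputed, consensus, obs)
        parts = [
            outcome_counts(imputed, consensus, obs, strata.keys(label))
            for label in ("UNANIMOUS", "LOW", "HIGH", "AT_MEDIAN")
        ]
        combined = sum(parts, OutcomeCounts())
        assert combined == pooled


def test_accuracy_is_prevalence_weighted_mix_of_se_and_sp(default_panel):
    table, _ = default_panel
    imputed = impute_unmentioned(table)
    consensus = build_consensus_table(imputed)
    for m in all_observer_metrics(imputed, consensus):
        if m.sensitivity is None or m.specificity is None:
            continue
        prev = (m.counts.tp + m.counts.fn) / m.counts.total
        mix = prev * m.sensitivity + (1 - prev) * m.specificity
        assert m.accuracy == pytest.approx(mix, abs=1e-12)


def test_rank_humans_reproduces_panel_ordering():
    accuracies = [
        0.910, 0.898, 0.889, 0.886, 0.882, 0.875,
        0.867, 0.862, 0.860, 0.856, 0.822,
    ]
    ranks = rank_humans(_metrics_from_values(accuracies), "accuracy")
    assert ranks.best.accuracy == pytest.approx(0.910)
    assert ranks.median.accuracy == pytest.approx(0.875)  # 6th of 11
    assert ranks.worst.accuracy == pytest.approx(0.822)


def test_rank_excludes_ai_and_undefined_and_handles_even_counts():
    ms = _metrics_from_values([0.95, 0.9, 0.8], is_ai={0})
    ranks = rank_humans(ms, "accuracy")
    assert ranks.best.accuracy == pytest.approx(0.9)  # AI never ranked

    ten = _metrics_from_values([v / 100 for v in range(90, 80, -1)])
    # 10 defined values: median is the 5th of the descending sort
    assert rank_humans(ten, "accuracy").median.accuracy == pytest.approx(0.86)

    single = _metrics_from_values([0.7])
    r = rank_humans(single, "accuracy")
    assert r.best is r.median is r.worst

    undefined = [
        ObserverMetrics("A", OutcomeCounts(tn=1), 1.0, None, 1.0),
        ObserverMetrics("B", OutcomeCounts(tp=1), 1.0, 1.0, None),
    ]
    assert rank_humans(undefined, "sensitivity").best.observer_id == "B"


def test_always_normal_benchmark_equals_normal_prevalence(default_panel):
    table, _ = default_panel
    imputed = impute_unmentioned(table)
    consensus = build_consensus_table(imputed)
    merged = imputed.records.merge(
        consensus.records, on=["study_id", "finding_code"]
    )
    expected = 1 - merged["consensus"].mean()
    assert always_normal_benchmark(imputed, consensus) == pytest.approx(expected)


def test_benchmark_is_zero_when_everything_abnormal():
    observers = [f"O{i}" for i in range(5)]
    rows = [("S1", f"C{k}", o, 1) for k in range(3) for o in observers]
    table = table_from_rows(rows, [(o, "S1") for o in observers])
    consensus = build_consensus_table(table)
    assert always_normal_benchmark(table, consensus) == 0.0
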