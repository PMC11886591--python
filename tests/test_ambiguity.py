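"""Assessment variance and the unanimous / low / high ambiguity split."""

import itertools

import numpy as np
import pandas as pd
import pytest

from readerstudy import (
    AT_MEDIAN,
    HIGH,
    LOW,
    UNANIMOUS,
    SyntheticConfig,
    assessment_variance,
    build_consensus_table,
    distribution_table,
    generate,
    impute_unmentioned,
    stratify,
    variance_table,
)


def _var_frame(values, n_observers=6):
    return pd.DataFrame(
        {
            "study_id": "S1",
            "finding_code": [f"F{i}" for i in range(len(values))],
            "n_observers": n_observers,
            "variance": values,
        }
    )


@pytest.mark.parametrize("reference", ["consensus", "mean"])
@pytest.mark.parametrize("value", [0, 1])
@pytest.mark.parametrize("n", [5, 6, 9, 12])
def test_unanimity_gives_exactly_zero_variance(reference, value, n):
    assert assessment_variance([value] * n, reference) == 0.0


def test_variance_worked_examples():
    assert assessment_variance([1, 1, 1, 0, 0], "consensus") == pytest.approx(0.4)
    assert assessment_variance([1, 1, 1, 0, 0, 0], "consensus") == pytest.approx(0.5)
    assert assessment_variance([1, 1, 1, 0, 0, 0], "mean") == pytest.approx(0.25)


def test_both_reference_modes_match_brute_force_on_all_length6_vectors():
    for bits in itertools.product((0, 1), repeat=6):
        mean = sum(bits) / 6
        cons = 1.0 if mean >= 0.5 else 0.0
        brute_cons = sum((b - cons) ** 2 for b in bits) / 6
        brute_mean = sum((b - mean) ** 2 for b in bits) / 6
        assert assessment_variance(bits, "consensus") == pytest.approx(brute_cons)
        assert assessment_variance(bits, "mean") == pytest.approx(brute_mean)


def test_consensus_variance_is_the_minority_fraction():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = rng.integers(5, 14)
        bits = rng.integers(0, 2, n)
        mean = bits.mean()
        assert assessment_variance(bits, "consensus") == pytest.approx(
            min(mean, 1 - mean)
        )


def test_stratify_strict_split_around_median():
    strata = stratify(_var_frame([0.0, 0.2, 0.2, 0.4, 0.4]))
    assert strata.median_variance == pytest.approx(0.3)
    counts = strata.counts()
    assert counts == {UNANIMOUS: 1, LOW: 2, HIGH: 2, AT_MEDIAN: 0}


def test_finding_at_the_median_joins_neither_stratum():
    strata = stratify(_var_frame([0.2, 0.3, 0.4]))
    counts = strata.counts()
    assert counts[AT_MEDIAN] == 1
    assert counts[LOW] == counts[HIGH] == 1
    assert strata.keys(AT_MEDIAN) == {("S1", "F1")}


def test_all_unanimous_panel_has_empty_strata():
    strata = stratify(_var_frame([0.0, 0.0, 0.0]))
    assert strata.counts()[UNANIMOUS] == 3
    assert np.isnan(strata.median_variance)
    assert strata.keys(LOW) == set()
    assert strata.keys(HIGH) == set()


def test_partition_accounting_on_synthetic_panel(default_panel):
    table, _ = default_panel
    imputed = impute_unmentioned(table)
    consensus = build_consensus_table(imputed)
    strata = stratify(variance_table(imputed, consensus))
    counts = strata.counts()
    non_unanimous = (strata.records["variance"] > 0).sum()
    assert counts[LOW] + counts[HIGH] + counts[AT_MEDIAN] == non_unanimous
    assert counts[UNANIMOUS] + non_unanimous == len(strata.records)


def test_stratification_invariant_to_key_relabeling():
    base = _var_frame([0.1, 0.2, 0.3, 0.4])
    renamed = base.copy()
    renamed["finding_code"] = ["Z9", "Z8", "Z7", "Z6"]
    a = stratify(base).records["stratum"].tolist()
    b = stratify(renamed).records.sort_index()["stratum"].tolist()
    assert sorted(a) == sorted(b)


def test_difficult_findings_have_higher_mean_variance():
    """Bimodal difficulty (0 vs 0.5): the coin-flip component must raise
    the disagreement variance of the difficult findings."""
    config = SyntheticConfig(
        n_studies=40,
        findings_per_study=("fixed", 50),
        n_humans=6,
        human_read_fraction=1.0,
        ai_reads_all=False,
        difficulty_zero_prob=0.5,
        difficulty_range=(0.5, 0.5),
        mention_prob_normal=1.0,
        seed=23,
    )
    table, truth = generate(config)
    consensus = build_consensus_table(impute_unmentioned(table))
    var = variance_table(table, consensus).merge(
        truth, on=["study_id", "finding_code"]
    )
    easy = var.loc[var["difficulty"] == 0, "variance"].mean()
    hard = var.loc[var["difficulty"] > 0, "variance"].mean()
    assert hard > easy


def test_high_ambiguity_subsample_is_richer_in_abnormal(default_panel):
    """Observers are less sensitive than specific, so disagreement
    concentrates on abnormal findings: the high-ambiguity subsample has a
    higher abnormal share than the low-ambiguity one."""
    table, _ = default_panel
    imputed = impute_unmentioned(table)
    consensus = build_consensus_table(imputed)
    strata = stratify(variance_table(imputed, consensus))
    dist = distribution_table(imputed, consensus, strata)
    assert dist.loc["abnormal_pct", "high"] > dist.loc["abnormal_pct", "low"]
    # partition of observation counts
    assert (
        dist.loc["n_observations", "all"]
        >= dist.loc["n_observations", "no_unanimity"]
        >= dist.loc["n_observations", "low"] + dist.loc["n_observations", "high"]
    )
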