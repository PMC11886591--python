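import pandas as pd
import pytest

from readerstudy import FindingTable, SyntheticConfig, generate


def table_from_rows(rows, design, ai=None):
    """Build a FindingTable from (study, code, observer, assessment) tuples."""
    records = pd.DataFrame(
        rows, columns=["study_id", "finding_code", "observer_id", "assessment"]
    )
    d = pd.DataFrame(design, columns=["observer_id", "study_id"])
    return FindingTable(records=records, design=d, ai_observer_id=ai)


def unanimous_panel(n_findings=4, n_observers=6, value=0):
    """One study, every observer gives the same label to every finding."""
    observers = [f"O{i}" for i in range(n_observers)]
    rows = [
        ("S1", f"F{k}", obs, value) for k in range(n_findings) for obs in observers
    ]
    return table_from_rows(rows, [(obs, "S1") for obs in observers])


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic reader panel: 50 studies, 11 humans + AI."""
    table, truth = generate(SyntheticConfig(seed=7))
    return table, truth


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(
        n_studies=10,
        findings_per_study=("fixed", 20),
        n_humans=6,
        human_read_fraction=1.0,
        ai_reads_all=True,
        human_profiles=((1.0, 1.0),) * 6,
        ai_profile=(1.0, 1.0),
        difficulty_zero_prob=1.0,
        mention_prob_normal=1.0,
        seed=11,
    )
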