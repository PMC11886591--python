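"""Synthetic reader-panel generator with latent truth.

Emulates the design of a small-animal radiograph reader study: 50
studies, 11 human radiologists each reading about half the studies, one
AI observer reading all of them, roughly fifty findings per study with
16% abnormal prevalence, and heterogeneous observer skill.

Each finding carries a latent true state and a difficulty d in [0, 1].
An observer with sensitivity Se and specificity Sp labels the finding
correctly with probability

    (1 - d) * q + d * 0.5,      q = Se if truth is abnormal else Sp,

i.e. difficulty mixes the observer's skilled judgement with a fair coin.
Difficulty zero yields unanimity rates driven purely by skill; higher
difficulty injects disagreement, producing the unanimous / low- / high-
ambiguity structure the downstream stratification expects.

Abnormal calls are always written into the report; normal calls are
explicitly mentioned only with probability ``mention_prob_normal``,
leaving the rest to the unmentioned-means-normal imputation rule —
mirroring how real reports stay silent about most normal anatomy.

The latent truth is returned separately from the finding table so the
analysis pipeline never sees it; it exists only for parameter-recovery
tests.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValueValidationError
from .reading import FindingTable

#: Default human observer skill profiles (sensitivity, specificity):
#: eleven board-certified radiologists spanning Se 0.64-0.95 and
#: Sp 0.80-0.94, with the usual inverse coupling between the two.
DEFAULT_HUMAN_PROFILES: tuple[tuple[float, float], ...] = (
    (0.779, 0.936),
    (0.784, 0.921),
    (0.643, 0.926),
    (0.824, 0.899),
    (0.824, 0.899),
    (0.860, 0.878),
    (0.784, 0.883),
    (0.865, 0.861),
    (0.898, 0.852),
    (0.826, 0.861),
    (0.948, 0.798),
)

#: Default AI profile: more specific, less sensitive than most humans.
DEFAULT_AI_PROFILE: tuple[float, float] = (0.688, 0.944)

AI_OBSERVER_ID = "AI"

_MAX_READER_REDRAWS = 10_000


def _check_proportion(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


@dataclasses.dataclass
class SyntheticConfig:
    """Parameters of the synthetic reader panel.

    Attributes
    ----------
    n_studies
        Number of radiographic studies (cases).
    findings_per_study
        ``("poisson", mean)`` or ``("fixed", k)`` — distribution of the
        number of unique findings per study.
    n_humans
        Number of human observers.
    human_read_fraction
        Probability that a given human reads a given study.
    ai_reads_all
        Whether an AI observer reads every study.
    abnormal_prevalence
        Probability a finding's latent true state is abnormal.
    human_profiles
        Per-human (sensitivity, specificity); cycled if shorter than
        ``n_humans``.
    ai_profile
        (sensitivity, specificity) of the AI observer.
    difficulty_zero_prob
        Probability a finding is unambiguous (difficulty 0).
    difficulty_range
        (lo, hi) of the uniform difficulty draw for ambiguous findings.
    mention_prob_normal
        Probability an observer explicitly records a normal call.
    min_readers
        Minimum readers per study; reader assignments are redrawn until
        met (so the downstream consensus panel-size gate can be
        satisfied).  Set ``enforce_min_readers=False`` to disable.
    seed
        RNG seed; the same seed reproduces the output exactly.
    """

    n_studies: int = 50
    findings_per_study: tuple[str, float] = ("poisson", 51.0)
    n_humans: int = 11
    human_read_fraction: float = 0.5
    ai_reads_all: bool = True
    abnormal_prevalence: float = 0.16
    human_profiles: tuple[tuple[float, float], ...] = DEFAULT_HUMAN_PROFILES
    ai_profile: tuple[float, float] = DEFAULT_AI_PROFILE
    difficulty_zero_prob: float = 0.5
    difficulty_range: tuple[float, float] = (0.1, 0.6)
    mention_prob_normal: float = 0.3
    min_readers: int = 5
    enforce_min_readers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1 or self.n_humans < 1:
            raise ConfigError("need at least one study and one human observer")
        kind, param = self.findings_per_study
        if kind not in ("poisson", "fixed") or param <= 0:
            raise ConfigError(
                "findings_per_study must be ('poisson', mean>0) or ('fixed', k>0)"
            )
        _check_proportion(self.human_read_fraction, "human_read_fraction")
        _check_proportion(self.abnormal_prevalence, "abnormal_prevalence")
        _check_proportion(self.difficulty_zero_prob, "difficulty_zero_prob")
        _check_proportion(self.mention_prob_normal, "mention_prob_normal")
        lo, hi = self.difficulty_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigError("difficulty_range must satisfy 0 <= lo <= hi <= 1")
        for se, sp in (*self.human_profiles, self.ai_profile):
            _check_proportion(se, "sensitivity")
            _check_proportion(sp, "specificity")
        max_readers = self.n_humans + (1 if self.ai_reads_all else 0)
        if self.enforce_min_readers and max_readers < self.min_readers:
            raise ConfigError(
                f"cannot reach {self.min_readers} readers with "
                f"{self.n_humans} humans and ai_reads_all={self.ai_reads_all}"
            )
        expected = self.n_humans * self.human_read_fraction + (
            1 if self.ai_reads_all else 0
        )
        if expected < self.min_readers:
            warnings.warn(
                "expected readers per study "
                f"({expected:.1f}) below min_readers={self.min_readers}; "
                "reader assignments will be redrawn often",
                stacklevel=2,
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"synthetic config {path} must be a mapping")
        for key in ("findings_per_study", "difficulty_range", "ai_profile"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "human_profiles" in raw:
            raw["human_profiles"] = tuple(tuple(p) for p in raw["human_profiles"])
        raw.update(overrides)
        return cls(**raw)


def expected_assessment_accuracy(profile: tuple[float, float], d: float, truth: int) -> float:
    """Closed-form probability an observer labels a finding correctly.

    ``(1 - d) * q + d * 0.5`` with q = Se for abnormal truth, Sp for
    normal truth — the quantity parameter-recovery tests converge to.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueValidationError("difficulty must lie in [0, 1]")
    if truth not in (0, 1):
        raise ValueValidationError("truth must be binary 0/1")
    q = profile[0] if truth == 1 else profile[1]
    return (1.0 - d) * q + 0.5 * d


def _human_profile(config: SyntheticConfig, i: int) -> tuple[float, float]:
    return config.human_profiles[i % len(config.human_profiles)]


def generate(config: SyntheticConfig) -> tuple[FindingTable, pd.DataFrame]:
    """Draw one reader panel; returns ``(finding_table, truth_table)``.

    The finding table holds only the explicit records (run
    :func:`readerstudy.reading.impute_unmentioned` to complete it).  The
    truth table has one row per generated finding: ``study_id,
    finding_code, truth, difficulty`` — including findings that no
    observer happened to mention, which are absent from the finding
    table.
    """
    rng = np.random.default_rng(config.seed)
    human_ids = [f"R{i + 1:02d}" for i in range(config.n_humans)]
    profiles = {h: _human_profile(config, i) for i, h in enumerate(human_ids)}
    if config.ai_reads_all:
        profiles[AI_OBSERVER_ID] = config.ai_profile

    rec_study, rec_code, rec_obs, rec_assess = [], [], [], []
    design_rows: list[tuple[str, str]] = []
    truth_frames = []
    kind, param = config.findings_per_study
    lo, hi = config.difficulty_range

    for j in range(config.n_studies):
        sid = f"S{j + 1:03d}"
        if kind == "poisson":
            n_findings = int(rng.poisson(param))
            if n_findings == 0:
                n_findings = 1  # a report always contains something
        else:
            n_findings = int(param)
        codes = np.array([f"F{k + 1:03d}" for k in range(n_findings)])
        truth = (rng.random(n_findings) < config.abnormal_prevalence).astype("int8")
        ambiguous = rng.random(n_findings) >= config.difficulty_zero_prob
        difficulty = np.where(ambiguous, rng.uniform(lo, hi, n_findings), 0.0)

        for _ in range(_MAX_READER_REDRAWS):
            read_mask = rng.random(config.n_humans) < config.human_read_fraction
            readers = [h for h, r in zip(human_ids, read_mask) if r]
            if config.ai_reads_all:
                readers.append(AI_OBSERVER_ID)
            if not config.enforce_min_readers or len(readers) >= config.min_readers:
                break
        else:  # pragma: no cover - guarded by config validation
            raise ConfigError(f"could not assemble {config.min_readers} readers for {sid}")

        for obs in readers:
            design_rows.append((obs, sid))
            se, sp = profiles[obs]
            q = np.where(truth == 1, se, sp)
            p_correct = (1.0 - difficulty) * q + 0.5 * difficulty
            correct = rng.random(n_findings) < p_correct
            assessment = np.where(correct, truth, 1 - truth).astype("int8")
            mention = (assessment == 1) | (
                rng.random(n_findings) < config.mention_prob_normal
            )
            rec_study.append(np.full(mention.sum(), sid, dtype=object))
            rec_code.append(codes[mention])
            rec_obs.append(np.full(mention.sum(), obs, dtype=object))
            rec_assess.append(assessment[mention])

        truth_frames.append(
            pd.DataFrame(
                {
                    "study_id": sid,
                    "finding_code": codes,
                    "truth": truth,
                    "difficulty": difficulty,
                }
            )
        )

    records = pd.DataFrame(
        {
            "study_id": np.concatenate(rec_study),
            "finding_code": np.concatenate(rec_code),
            "observer_id": np.concatenate(rec_obs),
            "assessment": np.concatenate(rec_assess),
        }
    )
    records["mentioned"] = True
    design = pd.DataFrame(design_rows, columns=["observer_id", "study_id"])
    table = FindingTable(
        records=records,
        design=design,
        ai_observer_id=AI_OBSERVER_ID if config.ai_reads_all else None,
    )
    truth_table = pd.concat(truth_frames, ignore_index=True)
    return table, truth_table


def write_truth(truth_table: pd.DataFrame, path: str | Path) -> None:
    truth_table.to_csv(path, index=False)
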