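"""Synthetic judge-cohort generator.

Emulates a two-group study of dichotomous clinical risk-assessment
judgments: each judge (nurse student or experienced nurse) views every
scenario, decides whether the simulated patient is at risk of a critical
event, and rates their confidence in that judgment on a 0-100 scale.
Scenarios are split into an easy and a difficult stratum and into a
time-pressured and an unpressured block.

The generator has known ground-truth parameters (per-stratum accuracy,
per-group confidence bias, confidence precision, time-pressure shifts),
so downstream calibration statistics can be checked against analytic
expectations: with self-knowledge high, the expected over/underconfidence
of a group equals its confidence bias.

Randomness is hierarchical: one global seed spawns a cohort-level stream
(scenario ground truth) and one stream per judge, so adding judges to a
configuration never perturbs the draws of earlier judges.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Union

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

STUDENT = "student"
EXPERIENCED = "experienced"
GROUPS = (STUDENT, EXPERIENCED)

EASY = "easy"
DIFFICULT = "difficult"

AT_RISK = "at_risk"
NOT_AT_RISK = "not_at_risk"

#: Column order of the judgment-record table (and its CSV serialisation).
RECORD_COLUMNS = (
    "judge_id",
    "group",
    "scenario_id",
    "difficulty",
    "time_pressure",
    "judgment",
    "correct",
    "confidence",
)

_RECORD_DTYPES = {
    "judge_id": str,
    "group": str,
    "scenario_id": np.int64,
    "difficulty": str,
    "time_pressure": bool,
    "judgment": str,
    "correct": bool,
    "confidence": np.int64,
}


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


def _default_bias() -> dict[str, float]:
    # Group-level confidence biases mirroring the study's observed group
    # means: students slightly underconfident, experienced nurses
    # overconfident (probability scale, i.e. -1.05 and +6.56 points).
    return {STUDENT: -0.0105, EXPERIENCED: 0.0656}


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic judgment study.

    Defaults reproduce the emulated study design: 63 students and 34
    experienced nurses, 25 scenarios of which 8 are difficult, the first
    12 scenarios time-pressured, and stratum accuracies chosen so that
    overall expected accuracy is ~73.5%.

    Parameters
    ----------
    confidence_bias
        Signed offset added to each judge's confidence target on the
        probability scale. Either a single float applied to both groups
        or a mapping ``{"student": b_s, "experienced": b_e}``.
    self_knowledge
        Precision of confidence around its target: confidence is drawn
        from a normal law truncated to [0, 1] with standard deviation
        ``1 / self_knowledge``. Must be positive.
    tp_conf_shift_easy, tp_conf_shift_difficult
        Confidence-target shifts applied to time-pressured scenarios,
        per difficulty stratum. Opposite signs create a time-pressure x
        difficulty interaction on confidence.
    at_risk_base_rate
        Probability that a scenario's underlying patient is truly at
        risk; the study does not document its scenario mix, so this is
        an explicit parameter rather than a hidden constant.
    difficulty_blind_confidence
        When True, the confidence target ignores scenario difficulty and
        centres on the cohort's *overall* expected accuracy. This is the
        canonical mechanism producing a hard-easy effect: overconfidence
        on difficult items, underconfidence on easy ones.
    """

    n_students: int = 63
    n_experienced: int = 34
    n_scenarios: int = 25
    n_difficult: int = 8
    n_time_pressured: int = 12
    p_correct_easy: float = 0.82
    p_correct_difficult: float = 0.55
    confidence_bias: Union[float, Mapping[str, float]] = field(
        default_factory=_default_bias
    )
    self_knowledge: float = 10.0
    tp_conf_shift_easy: float = 0.03
    tp_conf_shift_difficult: float = -0.03
    at_risk_base_rate: float = 0.5
    difficulty_blind_confidence: bool = False
    seed: int = 0

    def bias_for(self, group: str) -> float:
        if isinstance(self.confidence_bias, Mapping):
            return float(self.confidence_bias[group])
        return float(self.confidence_bias)

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first invalid field."""
        for name in (
            "n_students",
            "n_experienced",
            "n_scenarios",
            "n_difficult",
            "n_time_pressured",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_difficult > self.n_scenarios:
            raise ConfigError("n_difficult exceeds n_scenarios")
        if self.n_time_pressured > self.n_scenarios:
            raise ConfigError("n_time_pressured exceeds n_scenarios")
        for name in ("p_correct_easy", "p_correct_difficult", "at_risk_base_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0) or not math.isfinite(value):
                raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")
        biases = (
            self.confidence_bias.values()
            if isinstance(self.confidence_bias, Mapping)
            else (self.confidence_bias,)
        )
        for b in biases:
            if not (-1.0 <= b <= 1.0):
                raise ConfigError(f"confidence_bias must lie in [-1, 1], got {b!r}")
        if isinstance(self.confidence_bias, Mapping):
            missing = set(GROUPS) - set(self.confidence_bias)
            if missing:
                raise ConfigError(f"confidence_bias mapping lacks groups: {sorted(missing)}")
        for name in ("tp_conf_shift_easy", "tp_conf_shift_difficult"):
            value = getattr(self, name)
            if not (-1.0 <= value <= 1.0):
                raise ConfigError(f"{name} must lie in [-1, 1], got {value!r}")
        if not (self.self_knowledge > 0) or not math.isfinite(self.self_knowledge):
            raise ConfigError(f"self_knowledge must be a positive finite number, got {self.self_knowledge!r}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["confidence_bias"], Mapping):
            d["confidence_bias"] = dict(d["confidence_bias"])
        return d


def difficult_scenario_ids(n_scenarios: int, n_difficult: int) -> frozenset[int]:
    """Deterministically spread the difficult scenarios across the deck.

    Evenly spaced 1-based ids, so that difficult items occur in both the
    time-pressured and unpressured blocks (a fully crossed difficulty x
    pressure layout whenever both strata are non-trivial).
    """
    if n_difficult == 0:
        return frozenset()
    pos = np.floor((np.arange(n_difficult) + 0.5) * n_scenarios / n_difficult)
    return frozenset((pos.astype(int) + 1).tolist())


def _judge_rng(seed: int, group_code: int, within_group_index: int) -> np.random.Generator:
    # keyed by (group, index within group) so growing either group never
    # perturbs the draws of judges already present
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, group_code, within_group_index))
    )


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _RECORD_DTYPES.items()})


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the full judgment-record table for one synthetic cohort.

    Returns one row per judge x scenario with columns
    :data:`RECORD_COLUMNS`. Correctness is Bernoulli with the stratum's
    accuracy; the stated judgment agrees with the scenario's ground
    truth exactly when correct. Confidence is a truncated normal on the
    probability scale around ``accuracy + bias + pressure shift``,
    scaled to 0-100 and rounded to an integer.
    """
    config.validate()
    n_judges = config.n_students + config.n_experienced
    n_scen = config.n_scenarios
    if n_judges == 0 or n_scen == 0:
        return _empty_records()

    scenario_ids = np.arange(1, n_scen + 1)
    difficult = np.isin(scenario_ids, list(difficult_scenario_ids(n_scen, config.n_difficult)))
    pressured = scenario_ids <= config.n_time_pressured
    p_correct = np.where(difficult, config.p_correct_difficult, config.p_correct_easy)
    overall_p = float(p_correct.mean())

    cohort_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    truth_at_risk = cohort_rng.random(n_scen) < config.at_risk_base_rate

    shift = np.where(
        pressured,
        np.where(difficult, config.tp_conf_shift_difficult, config.tp_conf_shift_easy),
        0.0,
    )
    base = np.full(n_scen, overall_p) if config.difficulty_blind_confidence else p_correct
    sd = 1.0 / config.self_knowledge

    judge_ids, groups, correct_all, judgment_all, conf_all = [], [], [], [], []
    for j in range(n_judges):
        if j < config.n_students:
            group, group_code, k = STUDENT, 0, j
            label = f"S{k + 1:03d}"
        else:
            group, group_code, k = EXPERIENCED, 1, j - config.n_students
            label = f"E{k + 1:03d}"
        rng = _judge_rng(config.seed, group_code, k)
        correct = rng.random(n_scen) < p_correct
        target = base + config.bias_for(group) + shift
        a = (0.0 - target) / sd
        b = (1.0 - target) / sd
        # inverse-CDF sampling keeps one vectorised call per judge
        u = rng.random(n_scen)
        x = truncnorm.ppf(u, a, b, loc=target, scale=sd)
        conf = np.rint(np.clip(x, 0.0, 1.0) * 100.0).astype(np.int64)
        judgment = np.where(correct, truth_at_risk, ~truth_at_risk)
        judge_ids.append(np.full(n_scen, label, dtype=object))
        groups.append(np.full(n_scen, group, dtype=object))
        correct_all.append(correct)
        judgment_all.append(judgment)
        conf_all.append(conf)

    records = pd.DataFrame(
        {
            "judge_id": np.concatenate(judge_ids),
            "group": np.concatenate(groups),
            "scenario_id": np.tile(scenario_ids, n_judges),
            "difficulty": np.where(np.tile(difficult, n_judges), DIFFICULT, EASY),
            "time_pressure": np.tile(pressured, n_judges),
            "judgment": np.where(np.concatenate(judgment_all), AT_RISK, NOT_AT_RISK),
            "correct": np.concatenate(correct_all),
            "confidence": np.concatenate(conf_all),
        }
    )
    return records.astype(_RECORD_DTYPES)


def write_records(records: pd.DataFrame, destination: Union[str, PathLike, IO[str]]) -> None:
    """Write a judgment-record table as UTF-8 CSV with the fixed header."""
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"record table lacks columns: {sorted(missing)}")
    records.loc[:, list(RECORD_COLUMNS)].to_csv(destination, index=False, lineterminator="\n")


def read_records(source: Union[str, PathLike, IO[str]]) -> pd.DataFrame:
    """Read a judgment-record CSV back into the canonical dtypes.

    Round-trips losslessly through :func:`write_records`.
    """
    df = pd.read_csv(source)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record file lacks columns: {sorted(missing)}")
    return df.loc[:, list(RECORD_COLUMNS)].astype(_RECORD_DTYPES)
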