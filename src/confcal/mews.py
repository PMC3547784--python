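"""Modified Early Warning Score (MEWS) scoring and difficulty labelling.

Each of five clinical cues — systolic blood pressure, heart rate,
respiratory rate, temperature and level of consciousness (AVPU) — is
converted to a 0-3 subscore via a cut-off table; the subscores are
summed to a 0-15 total. A total above a trigger threshold (default 5)
classifies the patient as at risk of a critical event.

The default cut-off table embedded in ``data/mews_subbe2001.csv``
transcribes the MEWS dialect of Subbe et al. (2001). Numeric intervals
are half-open, lower-inclusive ([lower, upper)); the top interval of
each cue additionally includes its upper bound, which is the
physiological limit of table coverage. A user-supplied table in the
same CSV layout can replace it for other dialects.

Scenario difficulty is defined by concordance between the score-based
prediction and the real patient outcome: scenarios where the rule's
prediction matches the outcome are easy, discordant ones difficult.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Union

import numpy as np
import pandas as pd

from .synthetic_data import DIFFICULT, EASY

CONSCIOUSNESS_LEVELS = ("alert", "voice", "pain", "unresponsive")

NUMERIC_CUES = ("systolic_bp", "heart_rate", "respiratory_rate", "temperature")

#: Physiological coverage of the default table (inclusive bounds):
#: systolic BP mmHg, heart rate /min, respiratory rate /min, temperature degC.
PHYSIOLOGICAL_BOUNDS = {
    "systolic_bp": (30.0, 300.0),
    "heart_rate": (10.0, 300.0),
    "respiratory_rate": (2.0, 80.0),
    "temperature": (25.0, 45.0),
}

#: Default at-risk trigger: total strictly greater than this value.
DEFAULT_RISK_THRESHOLD = 5

MAX_TOTAL = 15


class ScoringError(ValueError):
    """A vital-sign value falls outside the scoring table's coverage."""


@dataclass(frozen=True)
class VitalSigns:
    """Five-cue physiological state of one scenario.

    Numeric values must be finite and within the documented
    physiological bounds; consciousness must be an AVPU level.
    """

    systolic_bp: float
    heart_rate: float
    respiratory_rate: float
    temperature: float
    consciousness: str

    def __post_init__(self):
        for cue in NUMERIC_CUES:
            value = getattr(self, cue)
            lo, hi = PHYSIOLOGICAL_BOUNDS[cue]
            if not isinstance(value, (int, float)) or not math.isfinite(value) or not lo <= value <= hi:
                raise ValueError(f"{cue} must lie in [{lo}, {hi}], got {value!r}")
        if self.consciousness not in CONSCIOUSNESS_LEVELS:
            raise ValueError(
                f"consciousness must be one of {CONSCIOUSNESS_LEVELS}, got {self.consciousness!r}"
            )


@dataclass(frozen=True)
class ScenarioLabel:
    """MEWS scoring outcome for one scenario."""

    scenario_id: object
    subscores: dict
    total: int
    at_risk_predicted: bool
    outcome_critical: bool
    difficulty: str


class ScoringTable:
    """Cut-off table mapping cue values to 0-3 subscores.

    ``intervals`` maps each numeric cue to an ordered list of
    ``(lower, upper, score)`` rows; ``categories`` maps consciousness
    levels to scores.
    """

    def __init__(self, intervals: dict[str, list[tuple[float, float, int]]],
                 categories: dict[str, int]):
        for cue, rows in intervals.items():
            rows.sort(key=lambda r: r[0])
            for (lo, hi, sc), nxt in zip(rows, rows[1:]):
                if nxt[0] != hi:
                    raise ValueError(f"{cue} intervals are not contiguous at {hi}")
            for lo, hi, sc in rows:
                if not lo < hi:
                    raise ValueError(f"{cue} interval [{lo}, {hi}) is empty")
                if sc not in (0, 1, 2, 3):
                    raise ValueError(f"{cue} subscore {sc} outside 0-3")
        for level, sc in categories.items():
            if sc not in (0, 1, 2, 3):
                raise ValueError(f"consciousness subscore {sc} outside 0-3")
        self.intervals = intervals
        self.categories = categories

    @classmethod
    def from_csv(cls, source) -> "ScoringTable":
        df = pd.read_csv(source)
        intervals: dict[str, list[tuple[float, float, int]]] = {}
        categories: dict[str, int] = {}
        for _, row in df.iterrows():
            if isinstance(row["category"], str) and row["category"]:
                categories[row["category"]] = int(row["score"])
            else:
                intervals.setdefault(row["cue"], []).append(
                    (float(row["lower"]), float(row["upper"]), int(row["score"]))
                )
        return cls(intervals, categories)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "ScoringTable":
        with resources.files("confcal.data").joinpath("mews_subbe2001.csv").open() as fh:
            return cls.from_csv(fh)

    def score(self, cue: str, value: Union[float, str]) -> int:
        """Subscore for one cue; raises :class:`ScoringError` off-table."""
        if cue == "consciousness":
            if value not in self.categories:
                raise ScoringError(f"consciousness level {value!r} not in scoring table")
            return self.categories[value]
        rows = self.intervals.get(cue)
        if rows is None:
            raise ScoringError(f"no scoring rows for cue {cue!r}")
        for lower, upper, subscore in rows:
            if lower <= value < upper:
                return subscore
        # top interval is closed at the coverage limit
        if value == rows[-1][1]:
            return rows[-1][2]
        raise ScoringError(f"{cue} value {value!r} outside scoring table coverage")


def mews_subscores(v: VitalSigns, table: Optional[ScoringTable] = None) -> dict[str, int]:
    """The five 0-3 subscores for one set of vital signs."""
    table = table or ScoringTable.default()
    return {
        cue: table.score(cue, getattr(v, cue))
        for cue in (*NUMERIC_CUES, "consciousness")
    }


def mews_total(v: VitalSigns, table: Optional[ScoringTable] = None) -> int:
    return sum(mews_subscores(v, table).values())


def classify_risk(total: int, threshold: int = DEFAULT_RISK_THRESHOLD) -> bool:
    """At-risk flag: True iff the total score strictly exceeds the threshold."""
    if not isinstance(total, (int, np.integer)) or not 0 <= total <= MAX_TOTAL:
        raise ValueError(f"total must be an integer in [0, {MAX_TOTAL}], got {total!r}")
    return total > threshold


def classify_difficulty(at_risk_predicted: bool, outcome_critical: bool) -> str:
    """Easy when the score-based prediction matches the outcome, else difficult."""
    if at_risk_predicted is None or outcome_critical is None or (
        isinstance(outcome_critical, float) and math.isnan(outcome_critical)
    ):
        raise ValueError("outcome flag missing; cannot classify difficulty")
    return EASY if bool(at_risk_predicted) == bool(outcome_critical) else DIFFICULT


SCENARIO_COLUMNS = (
    "scenario_id",
    *NUMERIC_CUES,
    "consciousness",
    "outcome_critical",
)


def score_scenarios(
    scenarios: pd.DataFrame,
    table: Optional[ScoringTable] = None,
    threshold: int = DEFAULT_RISK_THRESHOLD,
) -> pd.DataFrame:
    """Score a scenario table (vital-sign columns + outcome_critical).

    Returns one row per scenario with the five subscores, the total, the
    at-risk prediction and the easy/difficult label.
    """
    missing = set(SCENARIO_COLUMNS) - set(scenarios.columns)
    if missing:
        raise ValueError(f"scenario table lacks columns: {sorted(missing)}")
    table = table or ScoringTable.default()
    rows = []
    for _, row in scenarios.iterrows():
        v = VitalSigns(
            systolic_bp=float(row["systolic_bp"]),
            heart_rate=float(row["heart_rate"]),
            respiratory_rate=float(row["respiratory_rate"]),
            temperature=float(row["temperature"]),
            consciousness=row["consciousness"],
        )
        subs = mews_subscores(v, table)
        total = sum(subs.values())
        predicted = classify_risk(total, threshold)
        outcome = row["outcome_critical"]
        difficulty = classify_difficulty(predicted, outcome)
        rows.append(
            {
                "scenario_id": row["scenario_id"],
                **{f"{cue}_score": sc for cue, sc in subs.items()},
                "mews_total": total,
                "at_risk_predicted": predicted,
                "outcome_critical": bool(outcome),
                "difficulty": difficulty,
            }
        )
    return pd.DataFrame(rows)
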