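"""Inferential comparisons of calibration statistics.

Three procedures, all two-sided with significance declared at p < 0.05
and no multiplicity adjustment:

* pooled-variance (Student) two-sample t test on per-judge statistics,
  df = n_a + n_b - 2;
* Wilcoxon rank-sum test via the tie-corrected normal approximation;
* factorial ANOVA with sequential (type I) sums of squares on
  judge x condition cell means, with terms for time pressure, task
  difficulty, participant, and the time pressure x difficulty
  interaction.

The ANOVA operates on the 2 x 2 table of per-judge cell means (one mean
per judge x time-pressure x difficulty cell), not on raw trials; with
J judges this gives a participant term with J - 1 df and a residual
with 4J - J - 3 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .calibration import to_probability

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def two_sample_t(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Independent two-sample Student t test (pooled variance)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not math.isfinite(t):
        raise ValueError("degenerate (zero pooled variance) samples")
    return TestResult(statistic=float(t), df=float(a.size + b.size - 2), p=float(p))


def rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Wilcoxon rank-sum z test with tie-corrected variance.

    z is based on group a's rank sum, so swapping the groups flips its
    sign; p is the two-sided normal tail probability.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    w = ranks[:n_a].sum()
    expected = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # every observation shares one value: the rank sum equals its
        # null expectation exactly, so report no evidence of a shift
        return TestResult(statistic=0.0, df=float("nan"), p=1.0)
    z = (w - expected) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), df=float("nan"), p=float(p))


CELL_COLUMNS = (
    "judge_id",
    "group",
    "time_pressure",
    "difficulty",
    "prop_correct",
    "mean_confidence",
    "n_items",
)


def cell_means(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw judgments to judge x time-pressure x difficulty cells."""
    if len(records) == 0:
        raise ValueError("cannot build cell means from an empty record table")
    work = records.assign(
        _conf_p=to_probability(records["confidence"]),
        _correct=records["correct"].astype(float),
    )
    grouped = (
        work.groupby(["judge_id", "group", "time_pressure", "difficulty"], sort=False)
        .agg(
            prop_correct=("_correct", "mean"),
            mean_confidence=("_conf_p", "mean"),
            n_items=("_correct", "size"),
        )
        .reset_index()
    )
    return grouped.loc[:, list(CELL_COLUMNS)]


ANOVA_TERMS = ("time_pressure", "difficulty", "participant", "time_pressure:difficulty")

_FORMULA_TERMS = {
    "C(time_pressure)": "time_pressure",
    "C(difficulty)": "difficulty",
    "C(judge_id)": "participant",
    "C(time_pressure):C(difficulty)": "time_pressure:difficulty",
    "Residual": "residual",
}


def factorial_anova(cells: pd.DataFrame, response: str) -> pd.DataFrame:
    """Sequential-SS factorial ANOVA on the cell-mean table.

    ``response`` is ``prop_correct`` or ``mean_confidence``. Every judge
    must contribute the complete 2 x 2 layout; incomplete judges are
    reported in the error.
    """
    if response not in ("prop_correct", "mean_confidence"):
        raise ValueError(f"unknown response {response!r}")
    counts = cells.groupby("judge_id", sort=False).size()
    incomplete = counts[counts != 4]
    if len(incomplete):
        raise ValueError(
            "incomplete 2x2 layout for judges: " + ", ".join(map(str, incomplete.index))
        )
    model = smf.ols(
        f"{response} ~ C(time_pressure) + C(difficulty) + C(judge_id)"
        " + C(time_pressure):C(difficulty)",
        data=cells,
    ).fit()
    table = sm.stats.anova_lm(model, typ=1)
    out = table.rename(index=_FORMULA_TERMS).reset_index(names="term")
    out = out.rename(columns={"sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"})
    out["df"] = out["df"].astype(int)
    # a term explaining exactly no variance is reported as F = 0 rather
    # than the 0/0 indeterminate a constant response would produce
    zero_ss = (out["term"] != "residual") & (out["sum_sq"] <= 1e-24)
    out.loc[zero_ss, "F"] = 0.0
    out.loc[zero_ss, "p"] = 1.0
    out["significant"] = out["p"] < ALPHA
    return out.loc[:, ["term", "df", "sum_sq", "F", "p", "significant"]]


#: Per-judge statistics compared between groups in the standard report.
GROUP_STATS = (
    "p_bar",
    "e_bar",
    "over_under",
    "calibration",
    "resolution",
    "normalised_resolution",
)


def compare_groups(
    per_judge: pd.DataFrame,
    stats_to_test: Sequence[str] = GROUP_STATS,
    group_a: str = "student",
    group_b: str = "experienced",
) -> pd.DataFrame:
    """Tidy table of group comparisons on per-judge statistics.

    For each statistic, runs both the pooled t test (difference of
    means) and the rank-sum test (difference of medians); statistics are
    oriented as group_a minus group_b.
    """
    a = per_judge[per_judge["group"] == group_a]
    b = per_judge[per_judge["group"] == group_b]
    rows = []
    for stat in stats_to_test:
        t_res = two_sample_t(a[stat], b[stat])
        rows.append(
            {
                "analysis": "t_test",
                "term": stat,
                "statistic": t_res.statistic,
                "df1": 1,
                "df2": t_res.df,
                "p": t_res.p,
                "significant": t_res.significant,
            }
        )
        z_res = rank_sum(a[stat], b[stat])
        rows.append(
            {
                "analysis": "rank_sum",
                "term": stat,
                "statistic": z_res.statistic,
                "df1": float("nan"),
                "df2": float("nan"),
                "p": z_res.p,
                "significant": z_res.significant,
            }
        )
    return pd.DataFrame(rows)


def anova_report(records: pd.DataFrame) -> pd.DataFrame:
    """Both factorial ANOVAs (accuracy and confidence) as one tidy table."""
    cells = cell_means(records)
    frames = []
    for response in ("prop_correct", "mean_confidence"):
        table = factorial_anova(cells, response)
        resid_df = int(table.loc[table["term"] == "residual", "df"].iloc[0])
        table = table[table["term"] != "residual"].copy()
        table.insert(0, "analysis", f"anova_{response}")
        table = table.rename(columns={"df": "df1", "F": "statistic"})
        table["df2"] = resid_df
        frames.append(
            table.loc[:, ["analysis", "term", "statistic", "df1", "df2", "p", "significant"]]
        )
    return pd.concat(frames, ignore_index=True)
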