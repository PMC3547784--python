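"""Calibration, over/underconfidence and resolution of probability judgments.

Implements the classical binned decomposition of judgment quality used
in confidence-calibration research. Confidence ratings (elicited on
0-100, handled internally on the probability scale) are grouped into
ordinal categories; within category *j* with :math:`n_j` responses,
:math:`\\bar p_j` is the mean confidence and :math:`\\bar e_j` the
proportion of correct judgments. With *n* total responses and overall
accuracy :math:`\\bar e`:

* calibration score
  :math:`\\frac{1}{n}\\sum_j n_j(\\bar p_j-\\bar e_j)^2`
  — 0 is perfect calibration, 1 the worst attainable;
* over/underconfidence :math:`p - e`, the signed gap between mean
  confidence and overall accuracy (positive = overconfident);
* resolution
  :math:`\\frac{1}{n}\\sum_j n_j(\\bar e_j-\\bar e)^2`,
  bounded above by the knowledge index :math:`\\bar e(1-\\bar e)`;
* normalised resolution, resolution divided by the knowledge index,
  a 0-1 discrimination measure comparable across judges.

Default binning pools all sub-0.5 ratings into a single bottom bin and
uses deciles from 0.5 upwards, so every response is counted and the
1/n weighting is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

#: One pooled bin below 0.5, then half-open deciles; the top bin includes 1.0.
DEFAULT_EDGES: tuple[float, ...] = (0.0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

#: Resolution may exceed the knowledge index by at most this much before
#: it is treated as an inconsistency rather than rounding error.
RESOLUTION_TOL = 1e-9


@dataclass(frozen=True)
class ConfidenceBin:
    """Summary of one confidence category."""

    j: int
    lower: float
    upper: float
    n: int
    p_bar: float  # mean confidence of members, probability scale (nan if empty)
    e_bar: float  # proportion correct among members (nan if empty)


class NormalisedResolution(NamedTuple):
    value: float
    degenerate: bool  # True when overall accuracy is 0 or 1


@dataclass(frozen=True)
class CalibrationSummary:
    """Per-judge (or per-stratum) calibration statistics."""

    n: int
    e_bar: float
    p_bar: float
    calibration: float
    over_under: float
    resolution: float
    normalised_resolution: float
    degenerate: bool
    bins: tuple[ConfidenceBin, ...]


def to_probability(confidence: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Map confidence ratings to the canonical probability scale.

    Ratings whose maximum exceeds 1 are interpreted as the 0-100
    elicitation scale and divided by 100; values already within [0, 1]
    pass through unchanged, so a table expressed on either scale yields
    identical statistics.
    """
    arr = _validated(confidence)
    if arr.size == 0:
        return arr
    return arr / _scale(arr)


def _validated(confidence) -> np.ndarray:
    arr = np.asarray(confidence, dtype=float)
    if arr.size and (np.any(~np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 100.0):
        raise ValueError("confidence ratings must lie in [0, 100]")
    return arr


def _scale(arr: np.ndarray) -> float:
    return 100.0 if arr.size and arr.max() > 1.0 else 1.0


def _check_edges(edges: Sequence[float]) -> np.ndarray:
    e = np.asarray(edges, dtype=float)
    if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if e[0] != 0.0 or e[-1] != 1.0:
        raise ValueError("bin edges must span [0, 1]")
    return e


def assign_bins(confidence_p: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Bin index per response: lower-inclusive half-open bins, top bin closed."""
    e = _check_edges(edges)
    idx = np.searchsorted(e, confidence_p, side="right") - 1
    return np.minimum(idx, e.size - 2)


def bin_confidence(
    records: pd.DataFrame, edges: Sequence[float] = DEFAULT_EDGES
) -> tuple[ConfidenceBin, ...]:
    """Group judgment records into confidence categories.

    Every record lands in exactly one bin; empty bins are retained with
    ``n = 0`` so the bin set always partitions [0, 1].
    """
    if len(records) == 0:
        raise ValueError("cannot bin an empty record table")
    e = _check_edges(edges)
    raw = _validated(records["confidence"])
    scale = _scale(raw)
    correct = np.asarray(records["correct"], dtype=float)
    idx = assign_bins(raw / scale, e)
    n_bins = e.size - 1
    counts = np.bincount(idx, minlength=n_bins)
    conf_sums = np.bincount(idx, weights=raw, minlength=n_bins)
    corr_sums = np.bincount(idx, weights=correct, minlength=n_bins)
    bins = []
    for j in range(n_bins):
        n_j = int(counts[j])
        # summing raw ratings and dividing once keeps constructions like
        # "ten ratings of 80, eight correct" exactly on the diagonal
        bins.append(
            ConfidenceBin(
                j=j,
                lower=float(e[j]),
                upper=float(e[j + 1]),
                n=n_j,
                p_bar=float(conf_sums[j] / (n_j * scale)) if n_j else float("nan"),
                e_bar=float(corr_sums[j] / n_j) if n_j else float("nan"),
            )
        )
    return tuple(bins)


def _check_bin_total(bins: Sequence[ConfidenceBin], n: int) -> None:
    if n <= 0:
        raise ValueError("n must be positive")
    if sum(b.n for b in bins) != n:
        raise ValueError("bin counts do not sum to n")


def calibration_score(bins: Sequence[ConfidenceBin], n: int) -> float:
    """Weighted squared confidence-accuracy deviation; 0 best, 1 worst."""
    _check_bin_total(bins, n)
    return float(sum(b.n * (b.p_bar - b.e_bar) ** 2 for b in bins if b.n) / n)


def over_underconfidence(records: pd.DataFrame) -> float:
    """Mean confidence minus proportion correct; negative = underconfident."""
    if len(records) == 0:
        raise ValueError("cannot score an empty record table")
    raw = _validated(records["confidence"])
    p_bar = float(raw.sum() / (raw.size * _scale(raw)))
    return p_bar - float(np.asarray(records["correct"], dtype=float).mean())


def resolution(bins: Sequence[ConfidenceBin], e_bar: float, n: int) -> float:
    """Weighted squared deviation of bin accuracies around overall accuracy."""
    _check_bin_total(bins, n)
    return float(sum(b.n * (b.e_bar - e_bar) ** 2 for b in bins if b.n) / n)


def normalised_resolution(resolution_score: float, e_bar: float) -> NormalisedResolution:
    """Resolution relative to its maximum, the knowledge index e(1-e).

    When every judgment shares one correctness value the knowledge index
    is 0 and no discrimination is measurable: the value is reported as
    0 with ``degenerate=True`` rather than as a 0/0 indeterminate.
    """
    knowledge = e_bar * (1.0 - e_bar)
    if knowledge == 0.0:
        return NormalisedResolution(0.0, True)
    if resolution_score > knowledge + RESOLUTION_TOL:
        raise ValueError(
            f"resolution {resolution_score} exceeds knowledge index {knowledge}"
        )
    return NormalisedResolution(min(resolution_score / knowledge, 1.0), False)


def summarise(
    records: pd.DataFrame, edges: Sequence[float] = DEFAULT_EDGES
) -> CalibrationSummary:
    """Compute the full set of calibration statistics for one record table."""
    if len(records) == 0:
        raise ValueError("cannot summarise an empty record table")
    bins = bin_confidence(records, edges)
    n = len(records)
    raw = _validated(records["confidence"])
    e_bar = float(np.asarray(records["correct"], dtype=float).mean())
    p_bar = float(raw.sum() / (n * _scale(raw)))
    res = resolution(bins, e_bar, n)
    nrs = normalised_resolution(res, e_bar)
    return CalibrationSummary(
        n=n,
        e_bar=e_bar,
        p_bar=p_bar,
        calibration=calibration_score(bins, n),
        over_under=p_bar - e_bar,
        resolution=res,
        normalised_resolution=nrs.value,
        degenerate=nrs.degenerate,
        bins=bins,
    )


#: Column order of the per-judge summary table.
SUMMARY_COLUMNS = (
    "judge_id",
    "group",
    "n",
    "e_bar",
    "p_bar",
    "calibration",
    "over_under",
    "resolution",
    "normalised_resolution",
    "degenerate_flag",
)


def summarise_by_judge(
    records: pd.DataFrame, edges: Sequence[float] = DEFAULT_EDGES
) -> pd.DataFrame:
    """One row of calibration statistics per judge.

    Judges are summarised individually and then compared across groups
    downstream; the row order follows first appearance in the table.
    """
    rows = []
    for judge_id, sub in records.groupby("judge_id", sort=False):
        s = summarise(sub, edges)
        rows.append(
            {
                "judge_id": judge_id,
                "group": sub["group"].iloc[0],
                "n": s.n,
                "e_bar": s.e_bar,
                "p_bar": s.p_bar,
                "calibration": s.calibration,
                "over_under": s.over_under,
                "resolution": s.resolution,
                "normalised_resolution": s.normalised_resolution,
                "degenerate_flag": s.degenerate,
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def summarise_strata(
    records: pd.DataFrame,
    by: Sequence[str],
    edges: Sequence[float] = DEFAULT_EDGES,
) -> pd.DataFrame:
    """Pooled calibration statistics per stratum (e.g. by difficulty).

    Unlike :func:`summarise_by_judge` this pools all records within a
    stratum, which is the appropriate unit for hard-easy comparisons
    where per-judge strata would be sparse.
    """
    rows = []
    for key, sub in records.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        s = summarise(sub, edges)
        row = dict(zip(by, key))
        row.update(
            n=s.n,
            e_bar=s.e_bar,
            p_bar=s.p_bar,
            calibration=s.calibration,
            over_under=s.over_under,
            resolution=s.resolution,
            normalised_resolution=s.normalised_resolution,
            degenerate_flag=s.degenerate,
        )
        rows.append(row)
    return pd.DataFrame(rows)
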