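"""Calibration curves (reliability diagrams).

A curve plots, per confidence bin, the proportion of correct judgments
(y) against the bin's mean confidence (x). Points on the 45-degree
identity line indicate perfect calibration; a curve below the line
indicates overconfidence, above it underconfidence. Ratings below a
minimum confidence (default 0.5) are excluded before binning, because
the sparse sub-0.5 categories would otherwise produce unstable points;
the excluded fraction is reported alongside the points.

Curves are computed on pooled records per stratum rather than averaged
over per-judge curves: with ~25 judgments per judge, per-judge bins are
too sparse to be meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .calibration import DEFAULT_EDGES, bin_confidence, to_probability


@dataclass(frozen=True)
class CurvePoint:
    """One non-empty confidence bin on a calibration curve."""

    lower: float
    upper: float
    x: float  # mean confidence of the bin, probability scale
    y: float  # proportion correct in the bin
    n: int


@dataclass(frozen=True)
class CurveResult:
    points: tuple[CurvePoint, ...]
    n_total: int  # records before exclusion
    n_excluded: int  # records dropped for confidence < min_confidence

    @property
    def excluded_fraction(self) -> float:
        return self.n_excluded / self.n_total


def curve_points(
    records: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_EDGES,
    min_confidence: float = 0.5,
) -> CurveResult:
    """Build the ordered point set of one calibration curve.

    ``min_confidence`` is on the probability scale (values above 1 are
    interpreted on the 0-100 scale). Empty bins yield no point; points
    are ordered by x.
    """
    if len(records) == 0:
        raise ValueError("cannot build a curve from an empty record table")
    if min_confidence > 1.0:
        min_confidence = min_confidence / 100.0
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    conf = to_probability(records["confidence"])
    keep = conf >= min_confidence
    n_total = len(records)
    n_excluded = int((~keep).sum())
    if n_excluded == n_total:
        raise ValueError("all records fall below min_confidence; no curve can be drawn")
    kept = records.loc[keep]
    bins = bin_confidence(kept, edges)
    points = tuple(
        CurvePoint(lower=b.lower, upper=b.upper, x=b.p_bar, y=b.e_bar, n=b.n)
        for b in bins
        if b.n > 0
    )
    points = tuple(sorted(points, key=lambda p: p.x))
    return CurveResult(points=points, n_total=n_total, n_excluded=n_excluded)


def deviation_summary(points: Sequence[CurvePoint]) -> float:
    """n-weighted mean horizontal-minus-vertical gap to the identity line.

    Positive values mean the curve lies below the 45-degree line
    (overconfidence); on the same post-exclusion records this equals the
    over/underconfidence score, since both are n-weighted means of
    confidence minus correctness.
    """
    if len(points) == 0:
        raise ValueError("deviation_summary requires at least one curve point")
    total = sum(p.n for p in points)
    return float(sum(p.n * (p.x - p.y) for p in points) / total)


CURVE_COLUMNS = ("bin_lower", "bin_upper", "x", "y", "n")


def curves_by_stratum(
    records: pd.DataFrame,
    by: Sequence[str],
    edges: Sequence[float] = DEFAULT_EDGES,
    min_confidence: float = 0.5,
) -> tuple[pd.DataFrame, dict[tuple, float]]:
    """One curve per stratum, as a tidy plot-ready table.

    Returns the concatenated point table (stratum columns + CURVE_COLUMNS)
    and a mapping from stratum key to its excluded fraction.
    """
    frames = []
    excluded: dict[tuple, float] = {}
    for key, sub in records.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        result = curve_points(sub, edges, min_confidence)
        frame = pd.DataFrame(
            [
                {
                    "bin_lower": p.lower,
                    "bin_upper": p.upper,
                    "x": p.x,
                    "y": p.y,
                    "n": p.n,
                }
                for p in result.points
            ]
        )
        for col, val in zip(reversed(by), reversed(key)):
            frame.insert(0, col, val)
        frames.append(frame)
        excluded[key] = result.excluded_fraction
    table = pd.concat(frames, ignore_index=True)
    return table, excluded


def plot_curves(curve_table: pd.DataFrame, by: Sequence[str], path) -> None:
    """Render a curve table to a vector figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", label="perfect calibration")
    for key, sub in curve_table.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        label = ", ".join(f"{c}={v}" for c, v in zip(by, key))
        ax.plot(sub["x"], sub["y"], marker="o", label=label)
    ax.set_xlabel("mean confidence")
    ax.set_ylabel("proportion correct")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
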