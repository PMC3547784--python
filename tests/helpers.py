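"""Independent oracles and record-table builders for the test suite.

Everything here recomputes quantities from first principles (pure-python
linear scans, explicit textbook formulas, numpy projection algebra) so
that the package's binned/vectorised implementations are checked against
genuinely separate code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def make_records(confidences, corrects, judge="J1", group="student"):
    """Minimal well-formed judgment-record table for calibration tests."""
    n = len(confidences)
    return pd.DataFrame(
        {
            "judge_id": [judge] * n,
            "group": [group] * n,
            "scenario_id": np.arange(1, n + 1),
            "difficulty": ["easy"] * n,
            "time_pressure": [False] * n,
            "judgment": ["at_risk"] * n,
            "correct": list(corrects),
            "confidence": list(confidences),
        }
    )


def adversarial_records(n_correct, n_incorrect):
    """Confidence 100 on every incorrect judgment, 0 on every correct one."""
    conf = [0] * n_correct + [100] * n_incorrect
    corr = [True] * n_correct + [False] * n_incorrect
    return make_records(conf, corr)


def random_record_table(rng, max_n=80):
    n = int(rng.integers(5, max_n))
    conf = rng.integers(0, 101, size=n)
    p = rng.uniform(0.1, 0.95)
    corr = rng.random(n) < p
    return make_records(conf.tolist(), corr.tolist())


def brute_force_stats(confidences, corrects, edges):
    """Per-record linear-scan computation of the three scores.

    Bins are found by scanning the edge list per record; bin means are
    accumulated in pure python. Returns (calibration, resolution,
    normalised_resolution, degenerate).
    """
    probs = [c / 100.0 if max(confidences) > 1 else float(c) for c in confidences]
    edges = list(edges)
    members: dict[int, list[int]] = {}
    for i, pr in enumerate(probs):
        for j in range(len(edges) - 1):
            in_bin = edges[j] <= pr < edges[j + 1] or (
                j == len(edges) - 2 and pr == edges[-1]
            )
            if in_bin:
                members.setdefault(j, []).append(i)
                break
    n = len(probs)
    e_bar = sum(1.0 for c in corrects if c) / n
    cal = 0.0
    res = 0.0
    for j, idx in members.items():
        n_j = len(idx)
        p_bar_j = sum(probs[i] for i in idx) / n_j
        e_bar_j = sum(1.0 for i in idx if corrects[i]) / n_j
        cal += n_j * (p_bar_j - e_bar_j) ** 2
        res += n_j * (e_bar_j - e_bar) ** 2
    cal /= n
    res /= n
    knowledge = e_bar * (1.0 - e_bar)
    if knowledge == 0.0:
        return cal, res, 0.0, True
    return cal, res, res / knowledge, False


def rank_sum_z_oracle(a, b):
    """Rank-sum z from an explicit midrank assignment."""
    pooled = list(a) + list(b)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        midrank = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = midrank
        i = j
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    w = sum(ranks[: n_a])
    expected = n_a * (n + 1) / 2.0
    tie_sizes = {}
    for v in pooled:
        tie_sizes[v] = tie_sizes.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_sizes.values()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    return (w - expected) / math.sqrt(var)


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t."""
    n_a, n_b = len(a), len(b)
    ma, mb = sum(a) / n_a, sum(b) / n_b
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    sp2 = (ssa + ssb) / (n_a + n_b - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / n_a + 1 / n_b))


def sequential_anova_oracle(cells, response):
    """Sequential (type I) sums of squares via numpy least squares.

    Fits the nested sequence intercept -> +time_pressure -> +difficulty
    -> +participant -> +interaction and differences the residual sums of
    squares. Returns {term: (ss, df, F, p)} plus the residual row.
    """
    y = cells[response].to_numpy(dtype=float)
    n = y.size

    def dummies(values):
        levels = sorted(set(map(str, values)))
        return np.column_stack([[1.0 if str(v) == lv else 0.0 for v in values] for lv in levels])

    tp = dummies(cells["time_pressure"])
    diff = dummies(cells["difficulty"])
    judge = dummies(cells["judge_id"])
    inter = np.column_stack(
        [tp[:, i] * diff[:, j] for i in range(tp.shape[1]) for j in range(diff.shape[1])]
    )
    blocks = [
        ("time_pressure", tp),
        ("difficulty", diff),
        ("participant", judge),
        ("time_pressure:difficulty", inter),
    ]

    def rss_and_rank(X):
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), rank

    X = np.ones((n, 1))
    prev_rss, prev_rank = rss_and_rank(X)
    out = {}
    for name, block in blocks:
        X = np.hstack([X, block])
        rss, rank = rss_and_rank(X)
        out[name] = (prev_rss - rss, rank - prev_rank)
        prev_rss, prev_rank = rss, rank
    resid_df = n - prev_rank
    result = {}
    for name, (ss, df) in out.items():
        ms = ss / df
        mse = prev_rss / resid_df
        f = ms / mse
        result[name] = (ss, df, f, float(stats.f.sf(f, df, resid_df)))
    result["residual"] = (prev_rss, resid_df, float("nan"), float("nan"))
    return result
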