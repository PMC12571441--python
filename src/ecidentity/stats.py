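"""Two-sample tests used throughout: Wilcoxon rank-sum and Student's t.

The Wilcoxon test is exact (full enumeration of the rank-sum distribution)
for small tie-free samples and otherwise uses the normal approximation with
tie-corrected variance and a continuity correction. Both paths report a
two-sided P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

EXACT_MAX_TOTAL = 16  # largest n+m for the automatic exact path


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    method: str  # wilcoxon_exact | wilcoxon_normal | t_test | welch_t_test
    n_x: int
    n_y: int
    summary: dict = field(default_factory=dict)
    direction: Optional[str] = None  # which sample is stochastically larger

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _summaries(x: np.ndarray, y: np.ndarray) -> dict:
    return {
        "mean_x": float(np.mean(x)),
        "mean_y": float(np.mean(y)),
        "median_x": float(np.median(x)),
        "median_y": float(np.median(y)),
    }


def _rank_sum_counts(n: int, m: int) -> np.ndarray:
    """counts[s] = number of size-n subsets of ranks 1..n+m with rank sum s.

    Classic DP over the Mann-Whitney rank-sum distribution; total mass is
    C(n+m, n).
    """
    N = n + m
    max_sum = n * N  # loose upper bound; true max is sum of top n ranks
    counts = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, N + 1):
        for j in range(min(rank, n), 0, -1):
            counts[j, rank:] += counts[j - 1, :-rank or None]
    return counts[n]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      mode: str = "auto") -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    mode='exact' enumerates the full rank-sum null distribution (tie-free
    samples only); mode='normal' uses the tie-corrected normal approximation
    with a 0.5 continuity correction; mode='auto' picks exact when
    n + m <= 16 and there are no ties.

    The reported statistic is the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    has_ties = np.unique(combined).size < combined.size
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0

    if mode == "exact" or (mode == "auto" and n + m <= EXACT_MAX_TOTAL and not has_ties):
        if has_ties:
            raise ValueError("exact Wilcoxon path requires tie-free samples")
        counts = _rank_sum_counts(n, m)
        total = counts.sum()
        sums = np.arange(counts.size)
        w_int = int(round(w))
        p_le = counts[sums <= w_int].sum() / total
        p_ge = counts[sums >= w_int].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "wilcoxon_exact"
    else:
        N = n + m
        mean_w = n * (N + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var_w = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if var_w <= 0:  # every value identical: no evidence of a shift
            p, z = 1.0, 0.0
        else:
            diff = w - mean_w
            cc = 0.5 * np.sign(diff)
            z = (diff - cc) / math.sqrt(var_w)
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "wilcoxon_normal"

    med_diff = float(np.median(x) - np.median(y))
    direction = "x" if med_diff > 0 else ("y" if med_diff < 0 else "tie")
    return GroupComparison(
        statistic=float(u), p_value=float(p), method=method,
        n_x=n, n_y=m, summary=_summaries(x, y), direction=direction,
    )


def student_t_two_sided(x: Sequence[float], y: Sequence[float],
                        equal_variance: bool = True) -> GroupComparison:
    """Two-tailed unpaired Student's t-test (pooled variance by default).

    ``equal_variance=False`` switches to the Welch variant
    (Satterthwaite degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if equal_variance:
        pooled = ((n - 1) * vx + (m - 1) * vy) / (n + m - 2)
        if pooled <= 0:
            raise ValueError("zero pooled variance: t statistic undefined")
        t = (x.mean() - y.mean()) / math.sqrt(pooled * (1 / n + 1 / m))
        df = n + m - 2
        method = "t_test"
    else:
        se2 = vx / n + vy / m
        if se2 <= 0:
            raise ValueError("zero variance in both samples")
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        df = se2**2 / ((vx / n) ** 2 / (n - 1) + (vy / m) ** 2 / (m - 1))
        method = "welch_t_test"
    p = min(1.0, 2.0 * sps.t.sf(abs(t), df))
    direction = "x" if t > 0 else ("y" if t < 0 else "tie")
    summary = _summaries(x, y)
    summary["df"] = float(df)
    return GroupComparison(
        statistic=float(t), p_value=float(p), method=method,
        n_x=n, n_y=m, summary=summary, direction=direction,
    )
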