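"""Comparison statistics for multi-seed optimizer experiments.

Implements the standard nonparametric toolkit for comparing stochastic
optimizers: pairwise Wilcoxon signed-rank tests at alpha = 0.05, Friedman
mean ranks (average ranking value, ARV; lower is better) over a methods x
cases score matrix, and the conventional "+/=/-" superiority labelling of a
reference method against a competitor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "friedman_mean_ranks",
    "plus_equal_minus",
]


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome; ``degenerate`` flags an all-zero-difference
    pair (no information, p reported as 1)."""

    statistic: float
    p_value: float
    n_effective: int
    degenerate: bool = False


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking (Wilcoxon's original
    treatment).  The exact null distribution is used for n <= 25: by full
    sign-assignment enumeration when n <= 12 (valid under ties), via the
    tie-free closed recursion otherwise; larger n falls back to the normal
    approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    diffs = a - b
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, degenerate=True)
    ranks = sps.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    statistic = float(min(w_plus, ranks.sum() - w_plus))
    has_ties = np.unique(np.abs(diffs)).size < n
    if n <= 12:
        # all 2^n sign assignments of the observed ranks (ties included)
        signs = np.array(
            np.meshgrid(*([[0.0, 1.0]] * n), indexing="ij")
        ).reshape(n, -1)
        w = ranks @ signs
        w_min = np.minimum(w, ranks.sum() - w)
        p = float(np.mean(w_min <= statistic + 1e-12))
        return WilcoxonResult(statistic, p, n)
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(
        diffs, zero_method="wilcox", alternative="two-sided", method=method,
        correction=False,
    )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n)


def friedman_mean_ranks(scores) -> np.ndarray:
    """Average ranking value per method from a methods x cases score matrix.

    Lower scores are better; per-case ranks use average ranks on ties.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need a methods x cases matrix with >= 2 of each")
    if np.isnan(scores).any():
        raise ValueError("score matrix has missing cells")
    ranks = np.apply_along_axis(sps.rankdata, 0, scores)
    return ranks.mean(axis=1)


def plus_equal_minus(
    p_values: Sequence[float],
    directions: Sequence[int],
    alpha: float = 0.05,
) -> tuple[int, int, int]:
    """Count cases where the reference method is significantly better (+),
    statistically indistinguishable (=), or significantly worse (-).

    ``directions`` holds +1 when the reference's result is better on that
    case, -1 when worse, 0 on an exact tie.
    """
    p_values = np.asarray(p_values, dtype=float)
    directions = np.asarray(directions, dtype=int)
    if p_values.shape != directions.shape:
        raise ValueError("p_values and directions must align")
    sig = p_values < alpha
    plus = int(np.sum(sig & (directions > 0)))
    minus = int(np.sum(sig & (directions < 0)))
    equal = int(p_values.size - plus - minus)
    return plus, equal, minus
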