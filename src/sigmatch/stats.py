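"""Evaluation statistics: smoothed metrics, binomial tests, log-rank
prioritization, accuracy-vs-coverage curves, and Bonferroni correction.

All proportion-like metrics here are "smoothed": the denominator carries an
extra +1 on the undesirable side, so that small samples are penalized
regardless of whether the raw proportion is above or below 50%.  A single
correct prediction therefore reports accuracy 1/2, not 1.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import AccuracyCurve

__all__ = [
    "smoothed_proportion",
    "smoothed_prf",
    "binom_ci",
    "binom_test",
    "logrank_prioritization",
    "accuracy_curve",
    "compare_coverage",
    "bonferroni",
]

#: above this n the exact binomial test switches to a continuity-corrected
#: normal approximation
EXACT_BINOM_LIMIT = 10_000


def smoothed_proportion(n_desired: int, n_undesired: int) -> float:
    """n_desired / (n_desired + n_undesired + 1).

    Unlike Bayes-Laplace smoothing this never rewards a small sample: the
    successes are not incremented, so the result always undershoots the raw
    proportion when the numerator is positive.
    """
    if n_desired < 0 or n_undesired < 0:
        raise ValueError("counts must be nonnegative")
    return n_desired / (n_desired + n_undesired + 1)


def smoothed_prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Smoothed precision, recall and F1.

    P = tp/(tp+fp+1), R = tp/(tp+fn+1), F1 = 3PR/(P+R+1).  The factor 3 and
    the +1 keep F1 on a [0, 1) scale while penalizing small counts.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    p = tp / (tp + fp + 1)
    r = tp / (tp + fn + 1)
    f1 = 3 * p * r / (p + r + 1)
    return p, r, f1


def binom_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Binomial CI around a proportion via the inverse binomial CDF.

    Both bounds are quantiles of Binomial(n, p-hat) with p-hat = successes/n
    (the smallest k whose CDF reaches the tail probability), divided by n —
    the construction used by spreadsheet BINOM.INV-based intervals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes outside [0, n]")
    alpha = 1.0 - level
    p_hat = successes / n
    lo = float(sps.binom.ppf(alpha / 2, n, p_hat)) / n
    hi = float(sps.binom.ppf(1 - alpha / 2, n, p_hat)) / n
    return lo, hi


def binom_test(successes: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test (normal approximation for huge n).

    The exact two-sided p sums every Binomial(n, p0) point mass that does
    not exceed the observed one.  Above :data:`EXACT_BINOM_LIMIT` trials a
    continuity-corrected normal approximation is used; p-values that
    underflow the float range are reported as 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes outside [0, n]")
    if n <= EXACT_BINOM_LIMIT:
        return float(sps.binomtest(successes, n, p0).pvalue)
    mu = n * p0
    sd = math.sqrt(n * p0 * (1 - p0))
    z = (abs(successes - mu) - 0.5) / sd
    z = max(z, 0.0)
    return float(min(1.0, 2 * sps.norm.sf(z)))


def logrank_prioritization(
    correct_scores: Sequence[float],
    incorrect_scores: Sequence[float],
) -> tuple[float, float]:
    """Signed two-group log-rank test on prediction scores.

    Each prediction "exits" when a rising score threshold passes its score,
    so scores play the role of fully observed event times.  The statistic is
    z = (E_correct - O_correct) / sqrt(V) with the grouped-tie
    hypergeometric variance: z > 0 when correct predictions persist to
    higher scores than incorrect ones, and swapping the groups negates z.
    Returns (z, two-sided normal p).  Either group smaller than 2 makes the
    comparison meaningless; (nan, nan) is returned.
    """
    correct = np.asarray(correct_scores, dtype=float)
    incorrect = np.asarray(incorrect_scores, dtype=float)
    if len(correct) < 2 or len(incorrect) < 2:
        return float("nan"), float("nan")
    times = np.concatenate([correct, incorrect])
    is_correct = np.concatenate(
        [np.ones(len(correct), bool), np.zeros(len(incorrect), bool)]
    )
    order = np.argsort(times)
    times, is_correct = times[order], is_correct[order]

    O = E = V = 0.0
    i, total = 0, len(times)
    while i < total:
        j = i
        while j < total and times[j] == times[i]:
            j += 1
        d = j - i  # events at this score (ties grouped)
        n_at_risk = total - i
        n1 = int(is_correct[i:].sum())  # correct still at risk
        d1 = int(is_correct[i:j].sum())
        O += d1
        E += d * n1 / n_at_risk
        if n_at_risk > 1:
            V += (
                d * (n1 / n_at_risk) * (1 - n1 / n_at_risk)
                * (n_at_risk - d) / (n_at_risk - 1)
            )
        i = j
    if V <= 0:
        return 0.0, 1.0
    z = (E - O) / math.sqrt(V)
    p = float(2 * sps.norm.sf(abs(z)))
    return float(z), p


def accuracy_curve(
    scores: Sequence[float],
    correct: Sequence[bool],
    *,
    directions: Sequence[int] | None = None,
) -> AccuracyCurve | dict[int, AccuracyCurve]:
    """Smoothed accuracy swept over descending score thresholds.

    At each distinct score s the curve reports the number of correct and
    incorrect predictions scoring >= s and their smoothed accuracy.  When
    ``directions`` is given, positive and negative predictions are assessed
    separately and a {direction: curve} map is returned — directional bias
    shared with the reference database would otherwise masquerade as
    prioritization.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(correct, dtype=bool)
    if scores.shape != flags.shape:
        raise ValueError("scores and correctness flags differ in length")
    if directions is not None:
        directions = np.asarray(directions)
        return {
            int(d): accuracy_curve(scores[directions == d], flags[directions == d])
            for d in np.unique(directions)
        }
    rows = []
    for s in np.unique(scores)[::-1]:
        at = scores >= s
        n_corr = int(flags[at].sum())
        n_inc = int((~flags[at]).sum())
        rows.append(
            {
                "score": float(s),
                "n_correct": n_corr,
                "n_incorrect": n_inc,
                "accuracy": smoothed_proportion(n_corr, n_inc),
            }
        )
    table = pd.DataFrame(
        rows, columns=["score", "n_correct", "n_incorrect", "accuracy"]
    )
    return AccuracyCurve(table)


def compare_coverage(
    curve_a: AccuracyCurve, curve_b: AccuracyCurve
) -> tuple[float, float]:
    """Binomial coverage comparison over predictor A's accuracy levels.

    For each distinct accuracy level achieved by A, asks whether B attains a
    strictly larger number of correct predictions at accuracy >= that level.
    Returns (proportion of levels where B wins, exact two-sided binomial p
    against a chance rate of 0.5).
    """
    levels = curve_a.levels
    if len(levels) == 0:
        raise ValueError("predictor A achieved no accuracy levels")
    wins = sum(
        1 for lv in levels if curve_b.coverage_at(lv) > curve_a.coverage_at(lv)
    )
    return wins / len(levels), binom_test(wins, len(levels), 0.5)


def bonferroni(p: float, m: int) -> float:
    """Multiply a p-value by the number of hypotheses, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)
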