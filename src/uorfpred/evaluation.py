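"""Classifier evaluation: threshold sweep, LR+ selection, 2x2 statistics.

The sweep walks the score grid 0.00-0.95 in steps of 0.05 and, at each
cutoff, counts the confusion table of the hit rule (score strictly above
the cutoff AND at least one uORF) against the labels, yielding
sensitivity, specificity, positive predictive value and the positive
likelihood ratio LR+ = sensitivity / (1 - specificity).  The working
cutoff is the one maximizing LR+, reflecting a preference for specificity
over sensitivity when nominating targets.

The association helpers cover the 2x2 analyses around the classifier:
Fisher's exact test (two-sided, point-probability method), the Pearson
chi-square without continuity correction, the odds ratio and Yule's Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

THRESHOLD_GRID = tuple(round(0.05 * k, 2) for k in range(20))  # 0.00 .. 0.95


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table: rows = first classification, columns = second."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must contain at least one observation")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def threshold_sweep(
    scores,
    uorf_counts,
    labels,
    grid=THRESHOLD_GRID,
) -> pd.DataFrame:
    """Confusion metrics at every grid cutoff.

    Returns one row per threshold with columns threshold, tp, fp, tn, fn,
    sensitivity, specificity, ppv, lr_plus.  Undefined PPV (no predicted
    positives) is NaN, never 0; LR+ is +inf when specificity is 1 and
    sensitivity positive, NaN when both are degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    uorf_counts = np.asarray(uorf_counts, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores) == len(uorf_counts) == len(labels)):
        raise ValueError("scores, uorf_counts and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both classes for sweep metrics")
    rows = []
    for t in grid:
        pred = (scores > t) & (uorf_counts >= 1)
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        ppv = tp / (tp + fp) if (tp + fp) > 0 else math.nan
        if spec < 1.0:
            lr = sens / (1.0 - spec)
        else:
            lr = math.inf if sens > 0 else math.nan
        rows.append((t, tp, fp, tn, fn, sens, spec, ppv, lr))
    return pd.DataFrame(
        rows,
        columns=[
            "threshold", "tp", "fp", "tn", "fn",
            "sensitivity", "specificity", "ppv", "lr_plus",
        ],
    )


def select_threshold(metrics: pd.DataFrame) -> float:
    """Cutoff with the highest LR+ (infinite beats finite); ties broken by
    higher sensitivity, then by the lower threshold."""
    if len(metrics) == 0:
        raise ValueError("empty metrics")
    defined = metrics[~metrics["lr_plus"].isna()]
    if len(defined) == 0:
        raise ValueError("LR+ undefined at every threshold")
    best = defined.sort_values(
        ["lr_plus", "sensitivity", "threshold"],
        ascending=[False, False, True],
        kind="mergesort",
    ).iloc[0]
    return float(best["threshold"])


def fisher_exact(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p-value (point-probability method): the sum
    of probabilities, over tables with the observed margins, of tables no
    more probable than the observed one.  Degenerate margins give p = 1."""
    arr = t.to_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided").pvalue)


def chi_square_2x2(t: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1.

    Raises on a zero margin (an expected count of zero).
    """
    arr = t.to_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: expected counts are undefined")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def odds_ratio(t: TwoByTwo) -> float:
    """(a*d)/(b*c); +inf when b*c = 0 with a*d > 0, 0.0 when a*d = 0 with
    b*c > 0.  An all-zero diagonal pair on both products is an error."""
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        if ad == 0:
            raise ValueError("odds ratio undefined: both products are zero")
        return math.inf
    return ad / bc


def yules_q(or_value: float) -> float:
    """Yule's Q = (OR - 1)/(OR + 1), the 2x2 association coefficient in
    [-1, 1]; an infinite odds ratio maps to 1."""
    if or_value < 0:
        raise ValueError("odds ratio must be non-negative")
    if math.isinf(or_value):
        return 1.0
    return (or_value - 1.0) / (or_value + 1.0)
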