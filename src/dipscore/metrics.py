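"""Classification and association statistics.

AUC is computed as the normalized rank statistic (concordant pairs plus
half the tied pairs over all positive-negative pairs), which is exact
under ties.  The two-sample location test enumerates the permutation
distribution exactly for small groups and otherwise uses the
tie-corrected normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from dipscore.scorecard import as_label_array

# Exact enumeration is used when C(n_a + n_b, n_a) is at most this.
_EXACT_ENUM_LIMIT = 200_000


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and the derived rates at a fixed threshold.

    Rates with a zero denominator are reported as 0.0 and flagged in
    ``undefined`` (subset of {"sensitivity", "specificity", "mcc"}).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    undefined: frozenset[str] = frozenset()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(
    scores: Sequence[float], labels: Sequence, threshold: float
) -> ConfusionSummary:
    """Confusion summary for predictions ``score > threshold``."""
    s = np.asarray(scores, dtype=float)
    y = as_label_array(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    if len(s) == 0:
        raise ValueError("need at least one sample")
    pred = s > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))
    n = tp + fp + tn + fn
    undefined = set()
    accuracy = (tp + tn) / n
    if tp + fn == 0:
        sensitivity = 0.0
        undefined.add("sensitivity")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        specificity = 0.0
        undefined.add("specificity")
    else:
        specificity = tn / (tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
        undefined.add("mcc")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        mcc=mcc, undefined=frozenset(undefined),
    )


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based ROC AUC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = as_label_array(labels)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # midranks under ties
    rank_sum_pos = ranks[y].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("pearson_r inputs differ in length")
    if xv.size < 3:
        raise ValueError("pearson_r needs at least 3 points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def _u_from_ranks(pooled: np.ndarray, a_mask: np.ndarray) -> float:
    ranks = rankdata(pooled)
    n_a = int(a_mask.sum())
    return float(ranks[a_mask].sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample rank-sum test; returns (U for group a, two-sided p).

    U uses midranks under ties.  The p-value is computed by exhaustive
    enumeration of all group assignments when the number of combinations
    is small (covers every case with n_a*n_b <= 200 and balanced groups
    up to 9 per side); otherwise the tie-corrected normal approximation
    (no continuity correction) is used.  The permutation distribution of
    U is symmetric about n_a*n_b/2 even under ties, so the two-sided p is
    the probability of |U - n_a*n_b/2| at least as large as observed.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    n_a, n_b = av.size, bv.size
    n = n_a + n_b
    pooled = np.concatenate([av, bv])
    mask = np.zeros(n, dtype=bool)
    mask[:n_a] = True
    u = _u_from_ranks(pooled, mask)
    mu = n_a * n_b / 2.0

    if math.comb(n, n_a) <= _EXACT_ENUM_LIMIT:
        observed = abs(u - mu)
        ranks = rankdata(pooled)  # fixed across assignments
        offset = n_a * (n_a + 1) / 2.0
        hits = total = 0
        for idx in combinations(range(n), n_a):
            u_perm = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= observed - 1e-12:
                hits += 1
        return u, hits / total

    # Normal approximation with tie correction.
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # all values identical
        return u, 1.0
    z = (u - mu) / math.sqrt(sigma2)
    p = 2.0 * norm.sf(abs(z))
    return u, min(1.0, float(p))
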