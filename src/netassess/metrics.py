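"""Ranking-quality statistics: AUROC, AUPR (average precision), precision at recall.

All three operate on a *realized* ordering — ties are resolved upstream by
the deterministic ranking rule — and return NaN as the undefined marker when
either class is empty.  AUROC is the probability that a uniformly random
positive precedes a uniformly random negative (rank-sum form); AUPR is
step-wise average precision (mean, over positives in rank order, of the
precision at each positive's rank — no interpolation); precision-at-recall-r
is the precision at the smallest cutoff whose recall reaches r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

NAN = float("nan")


@dataclass(frozen=True)
class FoldMetrics:
    """Metrics of one evaluation; NaN fields mean undefined (empty class)."""

    auroc: float
    aupr: float
    prec_at_10_recall: float
    n_pos: int
    n_neg: int


def _mask(ranking, positives) -> np.ndarray:
    return np.fromiter((g in positives for g in ranking), dtype=bool, count=len(ranking))


def auroc_from_mask(mask: np.ndarray) -> float:
    P = int(mask.sum())
    N = mask.size - P
    if P == 0 or N == 0:
        return NAN
    # for each positive, count negatives ranked after it
    neg_before = np.cumsum(~mask)
    concordant = (N - neg_before[mask]).sum()
    return float(concordant) / (P * N)


def aupr_from_mask(mask: np.ndarray) -> float:
    P = int(mask.sum())
    if P == 0:
        return NAN
    pos_ranks = np.flatnonzero(mask) + 1
    return float(np.mean(np.arange(1, P + 1) / pos_ranks))


def precision_at_recall_from_mask(mask: np.ndarray, r: float = 0.10) -> float:
    P = int(mask.sum())
    if P == 0:
        return NAN
    k = max(1, math.ceil(r * P))
    rank = int(np.flatnonzero(mask)[k - 1]) + 1
    return k / rank


def auroc(ranking, positives) -> float:
    """Probability a random positive outranks a random negative."""
    return auroc_from_mask(_mask(ranking, positives))


def aupr(ranking, positives) -> float:
    """Average precision over the positives in rank order."""
    return aupr_from_mask(_mask(ranking, positives))


def precision_at_recall(ranking, positives, r: float = 0.10) -> float:
    """Precision at the smallest cutoff whose recall is at least *r*."""
    return precision_at_recall_from_mask(_mask(ranking, positives), r)


def compute_fold_metrics(ranking, positives) -> FoldMetrics:
    mask = _mask(ranking, positives)
    P = int(mask.sum())
    return FoldMetrics(
        auroc=auroc_from_mask(mask),
        aupr=aupr_from_mask(mask),
        prec_at_10_recall=precision_at_recall_from_mask(mask),
        n_pos=P,
        n_neg=mask.size - P,
    )
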