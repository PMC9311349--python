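"""Evaluation stack: confusion psychometrics, ROC/AUC, top-k ranking metrics,
and the domain-specific commonality and treatment-effectiveness percentages.

Set-valued recommendations against a clinician ground truth yield confusion
counts over a code universe, hence precision / recall / accuracy / F1 and
rank-sum AUC. Ranked recommendations are judged with P@k, AP@k / MAP@k and
DCG / NDCG@k. Commonality is the percentage of recommended codes that appear
in the clinician plan (a precision-style reading, selectable modes), and
treatment effectiveness (TE) is the percentage of recommended targets the
child actually mastered inside a month window.

Undefined cases (zero denominators, single-class labels, empty inputs) raise
:class:`~abarec.exceptions.UndefinedMetricError` rather than returning 0 —
these numbers feed clinical reports, where a silent zero misleads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cohort import MasteryRecord, TreatmentCode
from .exceptions import UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "classification_metrics",
    "roc_auc",
    "p_at_k",
    "ap_at_k",
    "map_at_k",
    "cg_at_k",
    "dcg_at_k",
    "idcg_at_k",
    "ndcg_at_k",
    "commonality",
    "treatment_effectiveness",
    "aggregate_mean",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(recommended: set, truth: set, universe: set) -> ConfusionCounts:
    """TP/FP/TN/FN of a set-valued recommendation against ground truth."""
    recommended, truth, universe = set(recommended), set(truth), set(universe)
    if not recommended <= universe:
        raise UndefinedMetricError(
            f"recommended items outside the universe: {recommended - universe}"
        )
    if not truth <= universe:
        raise UndefinedMetricError(f"truth items outside the universe: {truth - universe}")
    tp = len(recommended & truth)
    fp = len(recommended - truth)
    fn = len(truth - recommended)
    tn = len(universe - (recommended | truth))
    return ConfusionCounts(tp, fp, tn, fn)


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """precision, recall, accuracy, f1 from confusion counts.

    Each metric with a zero denominator raises individually; the others are
    still computed by calling with the metrics you need (this function raises
    on the first undefined one encountered, in the order listed).
    """
    out: dict[str, float] = {}
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive recommendations")
    out["precision"] = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no actual positives")
    out["recall"] = c.tp / (c.tp + c.fn)
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty universe")
    out["accuracy"] = (c.tp + c.tn) / c.total
    if 2 * c.tp + c.fp + c.fn == 0:
        raise UndefinedMetricError("f1 undefined: no positives anywhere")
    out["f1"] = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return out


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Computed through the rank-sum identity: AUC = (R_pos - n_pos(n_pos+1)/2)
    / (n_pos n_neg) with midranks, which equals the all-pairs count exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise UndefinedMetricError("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos + n_neg != labels.size:
        raise UndefinedMetricError("labels must be binary 0/1")
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)  # midranks handle ties
    r_pos = float(ranks[labels == 1].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def p_at_k(rel: Sequence[int], k: int) -> float:
    """Proportion of the top-k recommendations that are relevant."""
    if k < 1:
        raise UndefinedMetricError("k must be >= 1")
    if len(rel) < k:
        raise UndefinedMetricError(f"need at least k={k} relevance flags, got {len(rel)}")
    return float(sum(rel[:k]) / k)


def ap_at_k(rel: Sequence[int], k: int, m: int) -> float:
    """Average precision at depth k for one user.

    AP@k = (1/m') sum_{j<=k} P@j * rel(j) with m' = min(m, k), where m is the
    user's number of relevant items; m' keeps AP@k <= 1 on truncated lists,
    and AP = 0 when the user has no relevant items.
    """
    if k < 1:
        raise UndefinedMetricError("k must be >= 1")
    if m < 0:
        raise UndefinedMetricError("m must be nonnegative")
    m_eff = min(m, k)
    if m_eff == 0:
        return 0.0
    total = 0.0
    for j in range(1, min(k, len(rel)) + 1):
        if rel[j - 1]:
            total += p_at_k(rel, j)
    return total / m_eff


def map_at_k(aps: Iterable[float]) -> float:
    """Mean of per-user AP@k values."""
    aps = list(aps)
    if not aps:
        raise UndefinedMetricError("MAP undefined over an empty user set")
    return float(np.mean(aps))


def _padded(gains: Sequence[float], k: int) -> np.ndarray:
    g = np.asarray(gains, dtype=float)
    if (g < 0).any():
        raise UndefinedMetricError("gains must be nonnegative")
    if g.size < k:
        g = np.concatenate([g, np.zeros(k - g.size)])
    return g[:k]


def cg_at_k(gains: Sequence[float], k: int) -> float:
    """Cumulative gain: position-blind sum of the first k gains."""
    return float(_padded(gains, k).sum())


def dcg_at_k(gains: Sequence[float], k: int) -> float:
    """Discounted cumulative gain: sum_i G_i / log2(i + 1), i = 1..k."""
    g = _padded(gains, k)
    discounts = np.log2(np.arange(2, k + 2))
    return float((g / discounts).sum())


def idcg_at_k(gains: Sequence[float], k: int) -> float:
    """Ideal DCG: the DCG of the gains sorted descending."""
    g = np.sort(np.asarray(gains, dtype=float))[::-1]
    return dcg_at_k(g, k)


def ndcg_at_k(gains: Sequence[float], k: int) -> float:
    """DCG normalised by the ideal ordering; 0 by convention when IDCG = 0."""
    ideal = idcg_at_k(gains, k)
    if ideal == 0.0:
        return 0.0
    return dcg_at_k(gains, k) / ideal


COMMONALITY_MODES = ("precision", "recall", "jaccard")


def commonality(
    recommended: set, truth: set, mode: str = "precision"
) -> float:
    """Percentage overlap of a recommendation with the clinician plan.

    ``precision`` (default): 100 |rec & truth| / |rec| — the share of
    recommended codes that are relevant. ``recall``: denominator |truth|.
    ``jaccard``: denominator |rec | truth|.
    """
    recommended, truth = set(recommended), set(truth)
    if not recommended:
        raise UndefinedMetricError("commonality undefined for an empty recommendation")
    inter = len(recommended & truth)
    if mode == "precision":
        return 100.0 * inter / len(recommended)
    if mode == "recall":
        if not truth:
            raise UndefinedMetricError("recall-mode commonality undefined: empty truth")
        return 100.0 * inter / len(truth)
    if mode == "jaccard":
        return 100.0 * inter / len(recommended | truth)
    raise UndefinedMetricError(f"unknown commonality mode {mode!r}")


def treatment_effectiveness(
    recommended: Sequence[TreatmentCode],
    mastery: Sequence[MasteryRecord],
    window: tuple[int, int] = (1, 6),
) -> float:
    """Percentage of recommended codes mastered inside the month window.

    Target-level codes count when a mastered record for that exact code falls
    in ``window``; a domain-level code counts when at least one of its targets
    was mastered in the window.
    """
    recommended = list(recommended)
    if not recommended:
        raise UndefinedMetricError("treatment effectiveness undefined for empty recommendation")
    lo, hi = window
    if not (1 <= lo <= hi <= 6):
        raise UndefinedMetricError(f"window {window} must lie within months [1, 6]")
    mastered_targets = {
        rec.code for rec in mastery if rec.mastered and lo <= rec.month <= hi
    }
    mastered_domains = {c.parent for c in mastered_targets}
    hit = 0
    for code in recommended:
        if code.is_target:
            hit += code in mastered_targets
        else:
            hit += code in mastered_domains
    return 100.0 * hit / len(recommended)


def aggregate_mean(values: Sequence[float]) -> tuple[float, int]:
    """Arithmetic mean with its n, as reported in summary rows."""
    values = [float(v) for v in values]
    if not values:
        raise UndefinedMetricError("mean of an empty collection")
    if any(math.isnan(v) for v in values):
        raise UndefinedMetricError("mean over NaN values")
    return float(np.mean(values)), len(values)
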