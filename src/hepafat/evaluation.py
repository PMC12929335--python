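"""Threshold and ROC evaluation of binary steatosis classifiers.

Implements the evaluation machinery used to judge attenuation-based
steatosis markers: confusion-matrix metrics with balanced accuracy
(mean of sensitivity and specificity), threshold sweeps, trapezoidal
AUROC over all distinct score cutoffs, the DeLong paired test for
correlated ROC curves, and Spearman rank correlation.

Conventions: the positive class is steatosis.  For attenuation-like
scores where *lower* values indicate disease, callers pass
``direction="less_than"`` (sweeps) or negate scores for ROC so that an
informative marker yields AUROC > 0.5.  Reported percents are rounded
half-up to one decimal; full precision is retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ThresholdRow",
    "SweepResult",
    "RocResult",
    "DelongResult",
    "confusion_from_predictions",
    "metrics",
    "threshold_sweep",
    "roc_auc",
    "delong_compare",
    "spearman",
    "round_percent",
]


def round_percent(x: Optional[float]) -> Optional[float]:
    """Round a percent half-up to one decimal (table-report convention)."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion counts must total > 0")


@dataclass(frozen=True)
class MetricSet:
    """Percent-scale metrics; a metric with a zero denominator is None."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    balanced_accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def rounded(self) -> dict:
        return {
            "sensitivity": round_percent(self.sensitivity),
            "specificity": round_percent(self.specificity),
            "balanced_accuracy": round_percent(self.balanced_accuracy),
            "ppv": round_percent(self.ppv),
            "npv": round_percent(self.npv),
        }


def _ratio_percent(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """Sensitivity, specificity, balanced accuracy, PPV, NPV (percent)."""
    sens = _ratio_percent(counts.tp, counts.tp + counts.fn)
    spec = _ratio_percent(counts.tn, counts.tn + counts.fp)
    ba = None if sens is None or spec is None else (sens + spec) / 2.0
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=ba,
        ppv=_ratio_percent(counts.tp, counts.tp + counts.fp),
        npv=_ratio_percent(counts.tn, counts.tn + counts.fn),
    )


def confusion_from_predictions(predicted, truth) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(predicted & truth)),
        fp=int(np.sum(predicted & ~truth)),
        fn=int(np.sum(~predicted & truth)),
        tn=int(np.sum(~predicted & ~truth)),
    )


@dataclass(frozen=True)
class ThresholdRow:
    threshold: float
    counts: ConfusionCounts
    metrics: MetricSet


@dataclass(frozen=True)
class SweepResult:
    rows: tuple
    optimal: ThresholdRow


def threshold_sweep(scores, truth, thresholds: Sequence[float], direction: str) -> SweepResult:
    """Evaluate strict-inequality calls over a threshold grid.

    The optimal row maximises balanced accuracy (full precision); exact BA
    ties are broken toward the more specific threshold.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    if len(thresholds) == 0:
        raise ValueError("thresholds must be nonempty")
    if direction not in ("less_than", "greater_than"):
        raise ValueError("direction must be 'less_than' or 'greater_than'")

    rows = []
    for t in thresholds:
        predicted = scores < t if direction == "less_than" else scores > t
        counts = confusion_from_predictions(predicted, truth)
        rows.append(ThresholdRow(float(t), counts, metrics(counts)))

    def key(row: ThresholdRow):
        ba = row.metrics.balanced_accuracy
        spec = row.metrics.specificity
        return (-1.0 if ba is None else ba, -1.0 if spec is None else spec)

    optimal = max(rows, key=key)
    return SweepResult(rows=tuple(rows), optimal=optimal)


@dataclass(frozen=True)
class RocResult:
    points: tuple  # ((fpr, tpr), ...) from (0,0) to (1,1)
    auroc: float


def roc_auc(scores, truth) -> RocResult:
    """ROC curve over all distinct cutoffs; area by the trapezoidal rule.

    Higher scores must indicate the positive class.  Tied scores fall on a
    single ROC vertex, so the trapezoid through it credits ties with 1/2 —
    the curve's area equals the tie-corrected concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth)
    fps = np.cumsum(~sorted_truth)
    # keep only the last index of each tied-score run: one vertex per cutoff
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=tuple(zip(fpr.tolist(), tpr.tolist())), auroc=auc)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple:
    """Midrank placement values and AUC for one marker (DeLong building block)."""
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n  # P(neg < pos_i) with tie credit 1/2
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return v10, v01, auc


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    z: Optional[float]
    p: Optional[float]
    var_diff: float
    note: Optional[str] = None


def delong_compare(scores_a, scores_b, truth) -> DelongResult:
    """Paired comparison of two AUCs on the same subjects (DeLong test).

    Uses the midrank placement-value formulation of the AUC variance and
    covariance; ``z = (auc_a - auc_b) / sqrt(var(diff))`` is referred to the
    standard normal, two-sided.  Equal AUCs with a degenerate (zero)
    variance of the difference — e.g. identical score vectors — give z=0,
    p=1; unequal AUCs with a degenerate variance leave p undefined.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != truth.shape:
        raise ValueError("scores_a, scores_b and truth must be paired (equal length)")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")

    m = int(truth.sum())
    n = truth.size - m
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k], aucs[k] = _placements(s[truth], s[~truth])

    s10 = np.cov(v10)  # 2x2, ddof=1
    s01 = np.cov(v01)
    var = s10 / m + s01 / n
    var_diff = float(var[0, 0] + var[1, 1] - 2.0 * var[0, 1])

    auc_a, auc_b = float(aucs[0]), float(aucs[1])
    if var_diff <= 0 or not math.isfinite(var_diff):
        if math.isclose(auc_a, auc_b, abs_tol=1e-12):
            return DelongResult(auc_a, auc_b, 0.0, 1.0, max(var_diff, 0.0),
                                note="degenerate variance with equal AUCs")
        return DelongResult(auc_a, auc_b, None, None, max(var_diff, 0.0),
                            note="variance of the AUC difference is zero; z/p undefined")
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(z), float(p), var_diff)


def spearman(x, y) -> tuple:
    """Spearman rank correlation with midranks; p from the t-approximation.

    Returns ``(r, p)``; raises on constant input, for which the rank
    correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
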