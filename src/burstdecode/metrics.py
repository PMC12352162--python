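"""ROC/AUROC evaluation, Youden-optimal operating points, and AUROC
group comparisons."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMetrics",
    "auroc",
    "roc_points",
    "youden_point",
    "confusion_at_threshold",
    "compare_aurocs",
    "CHANCE_AUROC_CUTOFF",
]

#: AUROC above which an experiment counts as better than chance
CHANCE_AUROC_CUTOFF = 0.52


def auroc(probabilities, labels) -> float:
    """Area under the ROC curve; equals P(score+ > score-) with ties counting
    one half.  Raises on single-class labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(probabilities, dtype=float)))


def roc_points(probabilities, labels) -> pd.DataFrame:
    """ROC curve points at descending thresholds (fpr, tpr, threshold)."""
    fpr, tpr, thr = _sk_roc_curve(np.asarray(labels),
                                  np.asarray(probabilities, dtype=float))
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion-matrix summary at one operating threshold.

    PPV and F1 are reported as 0 when the classifier makes no positive
    predictions (sensitivity 0 likewise yields F1 = 0).
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    f1: float
    youden_j: float

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_at_threshold(probabilities, labels, threshold: float) -> ConfusionMetrics:
    """Metrics of the rule ``predict positive iff probability >= threshold``."""
    y = np.asarray(labels).astype(int)
    pred = (np.asarray(probabilities, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    acc = (tp + tn) / len(y)
    f1 = (2 * ppv * sens / (ppv + sens)) if ppv + sens else 0.0
    return ConfusionMetrics(threshold=float(threshold), sensitivity=sens,
                            specificity=spec, ppv=ppv, npv=npv, accuracy=acc,
                            f1=f1, youden_j=sens + spec - 1.0)


def youden_point(probabilities, labels) -> ConfusionMetrics:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward higher sensitivity.
    """
    curve = roc_points(probabilities, labels)
    j = curve.tpr - curve.fpr
    candidates = curve[j >= j.max() - 1e-12]  # ulp-tolerant tie set
    best = candidates.sort_values("tpr", ascending=False, kind="stable").index[0]
    thr = float(curve.threshold[best])
    if np.isinf(thr):  # sklearn's sentinel threshold above every score
        thr = float(np.max(probabilities)) + 1.0
    return confusion_at_threshold(probabilities, labels, thr)


def compare_aurocs(a, b, paired: bool) -> tuple[float, float]:
    """Two-sided t-test between two groups of AUROC values.

    Paired comparisons require equal lengths.  With identical paired lists
    the statistic is 0 and the p-value is reported as NaN (zero variance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two AUROC values per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    if np.isnan(t):  # zero-variance difference -> no evidence of a difference
        t = 0.0
    return float(t), float(p)
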