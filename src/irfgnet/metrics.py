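"""Multi-label evaluation metrics.

Everything the functional-group classifier is judged by: per-class
precision/recall/F1 with macro and support-weighted averages, average
precision (AP) and its unweighted mean (mAP), exact match rate (EMR) in
three forms (overall, bucketed by the number of groups per molecule, and
restricted to the first k classes in abundance order), and separate
presence/absence accuracies.

Zero-denominator conventions, stated once: precision with no predicted
positives is 1; recall with no true positives is 1; F1 is 0 when P + R = 0;
classes with an empty denominator are excluded from means with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "precision_recall_f1",
    "macro_and_weighted_f1",
    "average_precision",
    "mean_average_precision",
    "exact_match_rate",
    "emr_by_group_count",
    "emr_by_class_count",
    "presence_absence_accuracy",
    "abundance_order",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_pair(pred: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(pred)
    T = np.asarray(true)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: pred {P.shape} vs true {T.shape}")
    if P.ndim != 2:
        raise ValueError("expected (n_samples, n_classes) matrices")
    return P, T


def confusion(pred: np.ndarray, true: np.ndarray) -> list[ConfusionCounts]:
    """Per-class confusion counts over samples."""
    P, T = _check_pair(pred, true)
    out = []
    for c in range(P.shape[1]):
        p, t = P[:, c], T[:, c]
        out.append(
            ConfusionCounts(
                tp=int(np.sum((p == 1) & (t == 1))),
                fp=int(np.sum((p == 1) & (t == 0))),
                fn=int(np.sum((p == 0) & (t == 1))),
                tn=int(np.sum((p == 0) & (t == 0))),
            )
        )
    return out


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """(P, R, F1) with the stated zero-denominator conventions."""
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 1.0
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 1.0
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def macro_and_weighted_f1(
    f1s: np.ndarray, supports: np.ndarray
) -> tuple[float, float]:
    """Unweighted mean and support-weighted mean of per-class F1.

    The weighted average accounts for class-label imbalance by weighting
    each class by its number of true instances.
    """
    f1s = np.asarray(f1s, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if f1s.shape != supports.shape:
        raise ValueError("f1s and supports must align")
    if supports.sum() == 0:
        raise ValueError("all class supports are zero")
    return float(f1s.mean()), float(np.sum(f1s * supports) / supports.sum())


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP = sum over thresholds of (R_n - R_{n-1}) * P_n, high to low.

    The step-interpolated sum (no trapezoid): precision at each observed
    threshold is weighted by the recall increment it brings. AP of a perfect
    ranking is 1; a random scorer's expected AP is the positive prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    pred_pos = np.arange(1, len(s) + 1)
    # evaluate only at distinct thresholds: the last index of each tied run
    last_of_run = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    prec = tp[last_of_run] / pred_pos[last_of_run]
    rec = tp[last_of_run] / n_pos
    rec_prev = np.r_[0.0, rec[:-1]]
    return float(np.sum((rec - rec_prev) * prec))


def mean_average_precision(probs: np.ndarray, true: np.ndarray) -> float:
    """Unweighted mean of per-class AP; positive-free classes are excluded."""
    P = np.asarray(probs.probs if hasattr(probs, "probs") else probs, dtype=float)
    T = np.asarray(true)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch: probs {P.shape} vs true {T.shape}")
    aps = []
    for c in range(P.shape[1]):
        if T[:, c].sum() == 0:
            logger.warning("class %d has no positives; excluded from mAP", c)
            continue
        aps.append(average_precision(P[:, c], T[:, c]))
    if not aps:
        raise ValueError("no class with positive labels; mAP undefined")
    return float(np.mean(aps))


def exact_match_rate(pred: np.ndarray, true: np.ndarray) -> float:
    """Fraction of samples whose whole predicted row matches the truth."""
    P, T = _check_pair(pred, true)
    if len(P) == 0:
        raise ValueError("need at least one sample")
    return float(np.mean(np.all(P == T, axis=1)))


def emr_by_group_count(pred: np.ndarray, true: np.ndarray) -> pd.DataFrame:
    """EMR bucketed by the number of groups truly present in each molecule.

    Returns one row per observed popcount k with the bucket's individual
    EMR, the accumulated EMR over all samples with popcount <= k, and the
    bucket size. The accumulated EMR at the largest k equals the overall
    EMR of the included samples.
    """
    P, T = _check_pair(pred, true)
    if len(P) == 0:
        raise ValueError("need at least one sample")
    k = T.sum(axis=1)
    match = np.all(P == T, axis=1)
    rows = []
    for kk in np.unique(k):
        in_bucket = k == kk
        cum = k <= kk
        rows.append(
            {
                "n_groups": int(kk),
                "emr": float(match[in_bucket].mean()),
                "accumulated_emr": float(match[cum].mean()),
                "n": int(in_bucket.sum()),
            }
        )
    return pd.DataFrame(rows)


def abundance_order(true: np.ndarray) -> np.ndarray:
    """Class indices from most to least abundant (ties by class index)."""
    T = np.asarray(true)
    supports = T.sum(axis=0)
    return np.argsort(-supports, kind="stable")


def emr_by_class_count(
    pred: np.ndarray, true: np.ndarray, class_order: np.ndarray
) -> pd.DataFrame:
    """EMR restricted to the first k classes of ``class_order``, k = 1..K.

    With the conventional most-to-least-abundant order this traces how the
    exact-match criterion tightens as rarer classes are brought in; the
    sequence is non-increasing and ends at the overall EMR.
    """
    P, T = _check_pair(pred, true)
    order = np.asarray(class_order)
    K = P.shape[1]
    if sorted(order.tolist()) != list(range(K)):
        raise ValueError("class_order must be a permutation of all class indices")
    rows = []
    for k in range(1, K + 1):
        cols = order[:k]
        rows.append(
            {"n_classes": k, "emr": float(np.mean(np.all(P[:, cols] == T[:, cols], axis=1)))}
        )
    return pd.DataFrame(rows)


def presence_absence_accuracy(
    pred: np.ndarray, true: np.ndarray
) -> tuple[pd.DataFrame, float, float]:
    """Per-class accuracy on the positive and negative samples separately.

    Presence accuracy = tp/(tp+fn) over samples where the group is present
    (identical to recall); absence accuracy = tn/(tn+fp) over samples where
    it is absent. Classes with an empty denominator are excluded from the
    respective mean with a warning. Returns (per-class table, mean presence,
    mean absence).
    """
    counts = confusion(pred, true)
    rows = []
    for c, cc in enumerate(counts):
        pres = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else np.nan
        absn = cc.tn / (cc.tn + cc.fp) if cc.tn + cc.fp else np.nan
        if np.isnan(pres) or np.isnan(absn):
            logger.warning("class %d has an empty presence/absence denominator", c)
        rows.append({"class": c, "presence_accuracy": pres, "absence_accuracy": absn})
    frame = pd.DataFrame(rows)
    return (
        frame,
        float(frame["presence_accuracy"].mean(skipna=True)),
        float(frame["absence_accuracy"].mean(skipna=True)),
    )


@dataclass
class MetricsReport:
    """Aggregate report produced by :func:`evaluate`."""

    per_class: pd.DataFrame
    macro_f1: float
    weighted_f1: float
    map: float
    emr_overall: float
    emr_by_group_count: pd.DataFrame
    emr_by_class_count: pd.DataFrame
    mean_presence_accuracy: float
    mean_absence_accuracy: float

    def aggregates(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "map": self.map,
            "emr_overall": self.emr_overall,
            "mean_presence_accuracy": self.mean_presence_accuracy,
            "mean_absence_accuracy": self.mean_absence_accuracy,
        }


def evaluate(
    probs: np.ndarray,
    pred: np.ndarray,
    true: np.ndarray,
    class_names: list[str] | None = None,
) -> MetricsReport:
    """Full evaluation of crisp predictions + probabilities against truth."""
    P, T = _check_pair(pred, true)
    probs_arr = np.asarray(probs.probs if hasattr(probs, "probs") else probs, dtype=float)
    counts = confusion(P, T)
    supports = T.sum(axis=0)
    rows = []
    for c, cc in enumerate(counts):
        p, r, f1 = precision_recall_f1(cc)
        try:
            ap = average_precision(probs_arr[:, c], T[:, c])
        except ValueError:
            ap = np.nan
        rows.append(
            {
                "class": class_names[c] if class_names else str(c),
                "precision": p,
                "recall": r,
                "f1": f1,
                "ap": ap,
                "support": int(supports[c]),
            }
        )
    per_class = pd.DataFrame(rows)
    # macro/weighted over classes with nonzero support, matching the
    # exclusion-with-warning convention
    has_support = supports > 0
    if not has_support.any():
        raise ValueError("no class has positive support")
    if (~has_support).any():
        logger.warning(
            "classes %s have zero support; excluded from averages",
            np.flatnonzero(~has_support).tolist(),
        )
    macro, weighted = macro_and_weighted_f1(
        per_class["f1"].to_numpy()[has_support], supports[has_support]
    )
    pa_frame, mean_pres, mean_abs = presence_absence_accuracy(P, T)
    per_class["presence_accuracy"] = pa_frame["presence_accuracy"]
    per_class["absence_accuracy"] = pa_frame["absence_accuracy"]
    return MetricsReport(
        per_class=per_class,
        macro_f1=macro,
        weighted_f1=weighted,
        map=mean_average_precision(probs_arr, T),
        emr_overall=exact_match_rate(P, T),
        emr_by_group_count=emr_by_group_count(P, T),
        emr_by_class_count=emr_by_class_count(P, T, abundance_order(T)),
        mean_presence_accuracy=mean_pres,
        mean_absence_accuracy=mean_abs,
    )
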