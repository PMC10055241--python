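"""Per-class decision thresholds by F1 maximization.

The sigmoid outputs are converted to crisp labels by comparing against a
per-class cutoff. The default cutoff is 0.5; tuned cutoffs scan every
candidate threshold (the unique observed scores, plus 0.5) and keep the one
maximizing F1 on the tuning split — F1 is piecewise constant between
observed scores, so this candidate set is exhaustive. Ties break toward the
smallest maximizing threshold (favoring recall).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ClassThresholds", "PRCurve", "pr_curve", "optimal_threshold", "tune_all"]


@dataclass
class ClassThresholds:
    """Per-class probability cutoffs with provenance."""

    thresholds: np.ndarray
    provenance: str = "default_half"  # or "tuned"
    tuning_split: str = ""

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if ((self.thresholds <= 0) | (self.thresholds >= 1)).any():
            raise ValueError("thresholds must lie strictly inside (0, 1)")

    @classmethod
    def default(cls, n_classes: int) -> "ClassThresholds":
        return cls(np.full(n_classes, 0.5), provenance="default_half")

    def to_frame(self, names: list[str]) -> pd.DataFrame:
        return pd.DataFrame({"group": names, "threshold": self.thresholds})


@dataclass
class PRCurve:
    """Precision/recall along ascending candidate thresholds."""

    thresholds: np.ndarray
    precisions: np.ndarray
    recalls: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        self.recalls = np.asarray(self.recalls, dtype=float)
        if not (len(self.thresholds) == len(self.precisions) == len(self.recalls)):
            raise ValueError("misaligned PR curve vectors")
        if np.any(np.diff(self.recalls) > 1e-12):
            raise ValueError("recall must be non-increasing in the threshold")


def _counts_at(scores: np.ndarray, labels: np.ndarray, t: float) -> tuple[int, int, int]:
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, fn


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> PRCurve:
    """Precision/recall at every candidate threshold (ascending).

    Candidates are the sorted unique scores with 0.5 injected; a prediction
    is positive when score >= threshold. Precision with zero predicted
    positives is defined as 1.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if y.sum() == 0:
        raise ValueError("threshold tuning undefined without positive labels")
    cand = np.unique(np.concatenate([s, [0.5]]))
    prec, rec = np.empty(len(cand)), np.empty(len(cand))
    for i, t in enumerate(cand):
        tp, fp, fn = _counts_at(s, y, t)
        prec[i] = tp / (tp + fp) if tp + fp else 1.0
        rec[i] = tp / (tp + fn) if tp + fn else 1.0
    return PRCurve(thresholds=cand, precisions=prec, recalls=rec)


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """The candidate threshold maximizing F1 on (scores, labels).

    Ties break toward the smallest maximizing threshold.
    """
    curve = pr_curve(scores, labels)
    f1s = np.array([_f1(p, r) for p, r in zip(curve.precisions, curve.recalls)])
    return float(curve.thresholds[int(np.argmax(f1s))])


def tune_all(
    probs: np.ndarray, labels: np.ndarray, tuning_split: str = "train"
) -> ClassThresholds:
    """Per-class F1-optimal thresholds from a probability matrix.

    Classes without any positive tuning label fall back to 0.5 with a
    warning. The spec-level contract: for every class, F1 at the tuned
    threshold is >= F1 at 0.5 on the tuning data.
    """
    P = np.asarray(probs.probs if hasattr(probs, "probs") else probs, dtype=float)
    Y = np.asarray(labels)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: probs {P.shape} vs labels {Y.shape}")
    out = np.full(P.shape[1], 0.5)
    for c in range(P.shape[1]):
        if Y[:, c].sum() == 0:
            logger.warning("class %d has no positives; using default threshold 0.5", c)
            continue
        t = optimal_threshold(P[:, c], Y[:, c])
        # a threshold of exactly 0/1 cannot arise from sigmoid outputs, but
        # clamp defensively so ClassThresholds' open-interval invariant holds
        out[c] = min(max(t, 1e-9), 1 - 1e-9)
    return ClassThresholds(out, provenance="tuned", tuning_split=tuning_split)
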