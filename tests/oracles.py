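"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops, recomputing counts
from scratch, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def confusion_loops(pred, true, c):
    tp = fp = fn = tn = 0
    for i in range(len(pred)):
        p, t = pred[i][c], true[i][c]
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def prf_loops(pred, true, c):
    tp, fp, fn, tn = confusion_loops(pred, true, c)
    p = tp / (tp + fp) if tp + fp else 1.0
    r = tp / (tp + fn) if tp + fn else 1.0
    f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return p, r, f1


def macro_weighted_loops(pred, true):
    K = len(true[0])
    f1s, supports = [], []
    for c in range(K):
        _, _, f1 = prf_loops(pred, true, c)
        f1s.append(f1)
        supports.append(sum(row[c] for row in true))
    keep = [c for c in range(K) if supports[c] > 0]
    macro = sum(f1s[c] for c in keep) / len(keep)
    weighted = sum(f1s[c] * supports[c] for c in keep) / sum(supports[c] for c in keep)
    return macro, weighted


def average_precision_loops(scores, labels):
    """AP as the recall-increment-weighted precision sum over thresholds,
    traversed from the highest candidate threshold down."""
    n_pos = sum(labels)
    assert n_pos > 0
    cands = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in cands:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        pred_pos = sum(1 for s in scores if s >= t)
        precision = tp / pred_pos if pred_pos else 1.0
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def emr_loops(pred, true):
    hits = 0
    for i in range(len(pred)):
        if all(pred[i][c] == true[i][c] for c in range(len(true[0]))):
            hits += 1
    return hits / len(pred)


def emr_by_group_count_loops(pred, true):
    ks = sorted({sum(row) for row in true})
    out = {}
    for k in ks:
        bucket = [i for i in range(len(true)) if sum(true[i]) == k]
        cum = [i for i in range(len(true)) if sum(true[i]) <= k]
        ind = emr_loops([pred[i] for i in bucket], [true[i] for i in bucket])
        acc = emr_loops([pred[i] for i in cum], [true[i] for i in cum])
        out[k] = (ind, acc, len(bucket))
    return out


def emr_by_class_count_loops(pred, true, order):
    out = []
    for k in range(1, len(order) + 1):
        cols = order[:k]
        hits = 0
        for i in range(len(pred)):
            if all(pred[i][c] == true[i][c] for c in cols):
                hits += 1
        out.append(hits / len(pred))
    return out


def presence_absence_loops(pred, true):
    K = len(true[0])
    rows = []
    for c in range(K):
        pos = [i for i in range(len(true)) if true[i][c] == 1]
        neg = [i for i in range(len(true)) if true[i][c] == 0]
        pres = (
            sum(1 for i in pos if pred[i][c] == 1) / len(pos) if pos else np.nan
        )
        absn = (
            sum(1 for i in neg if pred[i][c] == 0) / len(neg) if neg else np.nan
        )
        rows.append((pres, absn))
    return rows


def best_f1_threshold_loops(scores, labels):
    """O(n^2) scan: recompute confusion counts from scratch per candidate."""
    best_t, best_f1 = None, -1.0
    for t in sorted(set(list(scores) + [0.5])):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
        p = tp / (tp + fp) if tp + fp else 1.0
        r = tp / (tp + fn) if tp + fn else 1.0
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = t, f1
    return best_t, best_f1


def f1_at_threshold_loops(scores, labels, t):
    tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < t and y == 1)
    p = tp / (tp + fp) if tp + fp else 1.0
    r = tp / (tp + fn) if tp + fn else 1.0
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)
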