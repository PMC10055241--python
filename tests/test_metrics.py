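"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest

import oracles

from irfgnet import metrics
from irfgnet.metrics import (
    ConfusionCounts,
    abundance_order,
    average_precision,
    confusion,
    emr_by_class_count,
    emr_by_group_count,
    exact_match_rate,
    macro_and_weighted_f1,
    mean_average_precision,
    precision_recall_f1,
    presence_absence_accuracy,
)


def random_instance(rng):
    n = int(rng.integers(1, 60))
    k = int(rng.integers(1, 8))
    true = (rng.random((n, k)) < rng.uniform(0.2, 0.8)).astype(int)
    pred = (rng.random((n, k)) < rng.uniform(0.2, 0.8)).astype(int)
    scores = np.round(rng.random((n, k)), 2)  # coarse: force score ties
    return pred, true, scores


def assert_instance_matches_oracles(pred, true, scores):
    """Compare every metric on one instance against the loop oracles."""
    n, k = true.shape
    counts = confusion(pred, true)
    for c in range(k):
        tp, fp, fn, tn = oracles.confusion_loops(pred, true, c)
        assert (counts[c].tp, counts[c].fp, counts[c].fn, counts[c].tn) == (tp, fp, fn, tn)
        assert counts[c].n == n
        p, r, f1 = precision_recall_f1(counts[c])
        po, ro, fo = oracles.prf_loops(pred, true, c)
        assert abs(p - po) < 1e-9 and abs(r - ro) < 1e-9 and abs(f1 - fo) < 1e-9
        if true[:, c].sum() > 0:
            ap = average_precision(scores[:, c], true[:, c])
            apo = oracles.average_precision_loops(list(scores[:, c]), list(true[:, c]))
            assert abs(ap - apo) < 1e-9

    if true.sum() > 0:
        f1s = np.array([precision_recall_f1(counts[c])[2] for c in range(k)])
        sup = true.sum(axis=0)
        keep = sup > 0
        macro, weighted = macro_and_weighted_f1(f1s[keep], sup[keep])
        mo, wo = oracles.macro_weighted_loops(pred.tolist(), true.tolist())
        assert abs(macro - mo) < 1e-9 and abs(weighted - wo) < 1e-9

        cols_with_pos = [c for c in range(k) if true[:, c].sum() > 0]
        m = mean_average_precision(scores[:, cols_with_pos], true[:, cols_with_pos])
        mo = np.mean(
            [
                oracles.average_precision_loops(list(scores[:, c]), list(true[:, c]))
                for c in cols_with_pos
            ]
        )
        assert abs(m - mo) < 1e-9

    assert abs(exact_match_rate(pred, true) - oracles.emr_loops(pred.tolist(), true.tolist())) < 1e-9

    table = emr_by_group_count(pred, true)
    want = oracles.emr_by_group_count_loops(pred.tolist(), true.tolist())
    for row in table.itertuples(index=False):
        ind, acc, size = want[row.n_groups]
        assert abs(row.emr - ind) < 1e-9
        assert abs(row.accumulated_emr - acc) < 1e-9
        assert row.n == size

    order = abundance_order(true)
    seq = emr_by_class_count(pred, true, order)["emr"].to_numpy()
    seq_o = oracles.emr_by_class_count_loops(pred.tolist(), true.tolist(), list(order))
    np.testing.assert_allclose(seq, seq_o, atol=1e-9)
    # monotone non-increasing, ends at overall EMR
    assert np.all(np.diff(seq) <= 1e-12)
    assert seq[-1] == pytest.approx(exact_match_rate(pred, true))

    frame, _, _ = presence_absence_accuracy(pred, true)
    for c, (pres, absn) in enumerate(oracles.presence_absence_loops(pred.tolist(), true.tolist())):
        got_p = frame["presence_accuracy"].iloc[c]
        got_a = frame["absence_accuracy"].iloc[c]
        assert (np.isnan(pres) and np.isnan(got_p)) or abs(got_p - pres) < 1e-9
        assert (np.isnan(absn) and np.isnan(got_a)) or abs(got_a - absn) < 1e-9


def test_all_metrics_agree_with_loop_oracles(rng):
    """200 random instances (n <= 60, K <= 8): every reported quantity
    matches an explicit-loop reimplementation to 1e-9."""
    for _ in range(200):
        pred, true, scores = random_instance(rng)
        assert_instance_matches_oracles(pred, true, scores)


def test_precision_recall_f1_conventions():
    assert precision_recall_f1(ConfusionCounts(1, 0, 0, 5)) == (1, 1, 1)
    p, r, f1 = precision_recall_f1(ConfusionCounts(2, 1, 1, 0))
    assert (p, r, f1) == pytest.approx((2 / 3, 2 / 3, 2 / 3))
    assert precision_recall_f1(ConfusionCounts(0, 0, 5, 5)) == (1, 0, 0)


def test_macro_weighted_worked_example():
    macro, weighted = macro_and_weighted_f1(np.array([1.0, 0.0]), np.array([9, 1]))
    assert macro == pytest.approx(0.5)
    assert weighted == pytest.approx(0.9)
    with pytest.raises(ValueError):
        macro_and_weighted_f1(np.array([1.0]), np.array([0]))


def test_average_precision_known_values():
    assert average_precision(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0])) == 1.0
    assert average_precision(np.array([0.9, 0.1]), np.array([0, 1])) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        average_precision(np.array([0.9, 0.1]), np.array([0, 0]))


def test_average_precision_matches_sklearn():
    sklearn = pytest.importorskip("sklearn.metrics")
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(3, 100))
        s = rng.random(n)
        y = (rng.random(n) < 0.4).astype(int)
        if y.sum() == 0:
            y[0] = 1
        assert average_precision(s, y) == pytest.approx(
            sklearn.average_precision_score(y, s), abs=1e-10
        )


def test_average_precision_invariant_under_monotone_transform(rng):
    for _ in range(30):
        n = int(rng.integers(3, 60))
        s = rng.random(n)
        y = (rng.random(n) < 0.5).astype(int)
        if y.sum() == 0:
            y[0] = 1
        a = average_precision(s, y)
        b = average_precision(np.exp(4 * s), y)
        assert a == pytest.approx(b, abs=1e-12)


def test_random_scores_ap_converges_to_prevalence():
    """Expected AP of a uniform-random scorer equals the positive
    prevalence. The expectation carries an O(1/n_pos) upward bias at
    finite n, so the Monte-Carlo band is 3 sigma plus a small bias
    allowance at n = 2000."""
    rng = np.random.default_rng(12)
    prevalence = 0.2
    n, reps = 2000, 600
    aps = np.array(
        [
            average_precision(rng.random(n), (rng.random(n) < prevalence).astype(int))
            for _ in range(reps)
        ]
    )
    se = aps.std() / np.sqrt(reps)
    assert abs(aps.mean() - prevalence) < 3 * se + 0.005


def test_mean_average_precision_compositional(rng):
    P = rng.random((40, 3))
    Y = (rng.random((40, 3)) < 0.5).astype(int)
    for c in range(3):
        if Y[:, c].sum() == 0:
            Y[0, c] = 1
    per = [average_precision(P[:, c], Y[:, c]) for c in range(3)]
    assert mean_average_precision(P, Y) == pytest.approx(np.mean(per), abs=1e-12)


def test_exact_match_rate_examples():
    t = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
    assert exact_match_rate(t, t) == 1.0
    p = t.copy()
    p[3] = [1, 0]
    assert exact_match_rate(p, t) == 0.75
    assert exact_match_rate(1 - t, t) == 0.0
    with pytest.raises(ValueError):
        exact_match_rate(t, t[:, :1])


def test_emr_by_group_count_cumulative_arithmetic():
    true = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 1, 1]])
    pred = np.array([[1, 0, 0], [0, 1, 0], [1, 0, 0], [0, 1, 0]])
    table = emr_by_group_count(pred, true).set_index("n_groups")
    assert table.loc[1, "emr"] == 1.0
    assert table.loc[2, "emr"] == 0.0
    assert table.loc[1, "accumulated_emr"] == 1.0
    assert table.loc[2, "accumulated_emr"] == 0.5
    assert table.loc[2, "accumulated_emr"] == pytest.approx(exact_match_rate(pred, true))


def test_emr_by_class_count_permutation_checks():
    true = np.array([[1, 0], [1, 1]])
    pred = np.array([[1, 0], [1, 0]])
    with pytest.raises(ValueError):
        emr_by_class_count(pred, true, np.array([0, 0]))
    seq = emr_by_class_count(pred, true, np.array([0, 1]))["emr"]
    assert seq.iloc[0] == 1.0 and seq.iloc[1] == 0.5


def test_emr_upper_bounded_by_per_class_accuracy(rng):
    for _ in range(20):
        pred, true, _ = random_instance(rng)
        emr = exact_match_rate(pred, true)
        per_class_acc = (pred == true).mean(axis=0)
        assert emr <= per_class_acc.min() + 1e-12


def test_presence_accuracy_equals_recall(rng):
    pred, true, _ = random_instance(rng)
    frame, _, _ = presence_absence_accuracy(pred, true)
    counts = confusion(pred, true)
    for c, cc in enumerate(counts):
        if cc.tp + cc.fn:
            _, recall, _ = precision_recall_f1(cc)
            assert frame["presence_accuracy"].iloc[c] == pytest.approx(recall)


def test_presence_absence_worked_example():
    true = np.array([[1], [1], [0], [0]])
    pred = np.array([[1], [0], [0], [1]])
    frame, mp, ma = presence_absence_accuracy(pred, true)
    assert frame["presence_accuracy"].iloc[0] == 0.5
    assert frame["absence_accuracy"].iloc[0] == 0.5


def test_evaluate_report_consistency(rng):
    pred, true, scores = random_instance(rng)
    while true.sum() == 0:
        pred, true, scores = random_instance(rng)
    report = metrics.evaluate(scores, pred, true)
    agg = report.aggregates()
    for v in agg.values():
        assert 0 <= v <= 1
    assert agg["emr_overall"] == pytest.approx(exact_match_rate(pred, true))
    # weighted F1 = support-weighted mean of per-class F1 (nonzero support)
    sup = report.per_class["support"].to_numpy()
    f1 = report.per_class["f1"].to_numpy()
    keep = sup > 0
    assert agg["weighted_f1"] == pytest.approx(np.sum(f1[keep] * sup[keep]) / sup[keep].sum())
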