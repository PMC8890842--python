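"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sscnn.metrics import (
    basic_metrics,
    confusion_matrix,
    macro_metrics,
    micro_metrics,
    per_class_counts,
    report_from_predictions,
    roc_auc,
)


# --------------------------------------------------------------------
# oracles: direct counting over label pairs / score pairs
# --------------------------------------------------------------------
def oracle_counts(truth, pred, c):
    tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
    fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
    fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
    tn = sum(1 for t, p in zip(truth, pred) if t != c and p != c)
    return tp, fp, fn, tn


def oracle_pairwise_auc(y, score):
    """AUC = fraction of correctly ordered (pos, neg) pairs, ties half."""
    pos = [s for s, t in zip(score, y) if t == 1]
    neg = [s for s, t in zip(score, y) if t == 0]
    if not pos or not neg:
        return np.nan
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_labelings(n_sets, rng):
    for _ in range(n_sets):
        noc = rng.integers(2, 6)
        n = rng.integers(noc, 40)
        truth = np.concatenate([np.arange(noc), rng.integers(0, noc, n - noc)])
        pred = rng.integers(0, noc, n)
        yield truth, pred, noc


# --------------------------------------------------------------------
# confusion matrix + per-class counts
# --------------------------------------------------------------------
def test_confusion_matrix_direct_counts():
    cm = confusion_matrix([0, 0, 1, 1], [0, 0, 0, 1], 2)
    assert cm.tolist() == [[2, 0], [1, 1]]


def test_confusion_matrix_joint_shuffle_invariance(rng):
    truth = rng.integers(0, 3, 50)
    pred = rng.integers(0, 3, 50)
    cm = confusion_matrix(truth, pred, 3)
    perm = rng.permutation(50)
    assert np.array_equal(cm, confusion_matrix(truth[perm], pred[perm], 3))


def test_confusion_matrix_rejects_out_of_range():
    with pytest.raises(ValueError):
        confusion_matrix([0, 3], [0, 1], 3)


def test_per_class_counts_worked_example():
    cm = np.array([[2, 0], [1, 1]])
    assert per_class_counts(cm, 0) == (2, 1, 0, 1)
    tp, fp, fn, tn = per_class_counts(cm, 1)
    assert (tp, fp, fn, tn) == (1, 0, 1, 2)
    assert tp + fp + fn + tn == cm.sum()


# --------------------------------------------------------------------
# oracle equivalence on random confusion matrices
# --------------------------------------------------------------------
def test_metrics_match_counting_oracle_on_200_random_sets():
    rng = np.random.default_rng(99)
    for truth, pred, noc in random_labelings(200, rng):
        cm = confusion_matrix(truth, pred, noc)
        basic = basic_metrics(cm)
        micro = micro_metrics(cm)
        macro = macro_metrics(cm)
        tps = fps = fns = 0
        pr, rc, f1 = [], [], []
        for c in range(noc):
            tp, fp, fn, tn = oracle_counts(truth, pred, c)
            assert per_class_counts(cm, c) == (tp, fp, fn, tn)
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = 2 * p * r / (p + r) if p + r else 0.0
            pr.append(p), rc.append(r), f1.append(f)
            tps, fps, fns = tps + tp, fps + fp, fns + fn
        assert basic["accuracy"] == pytest.approx(np.mean(truth == pred))
        assert basic["precision"] == pytest.approx(pr)
        assert basic["recall"] == pytest.approx(rc)
        assert basic["f1"] == pytest.approx(f1)
        mp = tps / (tps + fps)
        mr = tps / (tps + fns)
        assert micro["precision"] == pytest.approx(mp)
        assert micro["recall"] == pytest.approx(mr)
        assert micro["f1"] == pytest.approx(2 * mp * mr / (mp + mr) if mp + mr else 0.0)
        # single-label identity
        assert micro["precision"] == pytest.approx(basic["accuracy"])
        assert micro["recall"] == pytest.approx(basic["accuracy"])
        assert macro["precision"] == pytest.approx(np.mean(pr))
        assert macro["recall"] == pytest.approx(np.mean(rc))
        assert macro["f1"] == pytest.approx(np.mean(f1))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=60))
def test_micro_equals_accuracy_property(pairs):
    truth = [t for t, _ in pairs]
    pred = [p for _, p in pairs]
    cm = confusion_matrix(truth, pred, 3)
    micro = micro_metrics(cm)
    acc = basic_metrics(cm)["accuracy"]
    assert micro["precision"] == pytest.approx(acc)
    assert micro["recall"] == pytest.approx(acc)
    assert micro["f1"] == pytest.approx(acc)


def test_macro_micro_differ_under_imbalance():
    cm = np.array([[8, 0], [1, 1]])
    assert macro_metrics(cm)["precision"] != pytest.approx(micro_metrics(cm)["precision"])


def test_worked_example_2x2():
    cm = np.array([[2, 0], [1, 1]])
    basic = basic_metrics(cm)
    assert basic["accuracy"] == pytest.approx(0.75)
    assert basic["precision"][0] == pytest.approx(2 / 3)
    assert basic["recall"][0] == pytest.approx(1.0)
    assert micro_metrics(cm)["f1"] == pytest.approx(0.75)
    assert macro_metrics(cm)["precision"] == pytest.approx(5 / 6)


def test_zero_denominator_convention_warns():
    cm = np.array([[0, 2], [0, 2]])
    with pytest.warns(RuntimeWarning):
        basic = basic_metrics(cm)
    assert basic["precision"][0] == 0.0


def test_empty_confusion_matrix_rejected():
    with pytest.raises(ValueError):
        basic_metrics(np.zeros((3, 3), dtype=int))


# --------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------
def test_auc_matches_pairwise_oracle_on_50_random_score_sets():
    rng = np.random.default_rng(7)
    for _ in range(50):
        noc = int(rng.integers(2, 5))
        n = int(rng.integers(noc, 30))
        truth = np.concatenate([np.arange(noc), rng.integers(0, noc, n - noc)])
        raw = rng.random((n, noc))
        if rng.random() < 0.3:  # force score ties sometimes
            raw = np.round(raw, 1)
        probs = raw / raw.sum(axis=1, keepdims=True)
        res = roc_auc(truth, probs)
        onehot = np.eye(noc)[truth]
        for c in range(noc):
            assert res["per_class"][c] == pytest.approx(
                oracle_pairwise_auc(onehot[:, c], probs[:, c])
            )
        assert res["micro"] == pytest.approx(
            oracle_pairwise_auc(onehot.ravel(), probs.ravel())
        )
        assert res["macro"] == pytest.approx(np.nanmean(res["per_class"]))


def test_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    truth = rng.integers(0, 3, 60)
    truth[:3] = [0, 1, 2]
    raw = rng.random((60, 3))
    probs = raw / raw.sum(axis=1, keepdims=True)
    res = roc_auc(truth, probs)
    assert res["macro"] == pytest.approx(
        roc_auc_score(truth, probs, multi_class="ovr", average="macro")
    )
    onehot = np.eye(3)[truth]
    assert res["micro"] == pytest.approx(roc_auc_score(onehot.ravel(), probs.ravel()))


def test_auc_perfect_and_uninformative():
    truth = [0, 0, 1, 1]
    perfect = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    res = roc_auc(truth, perfect)
    assert res["per_class"] == pytest.approx([1.0, 1.0])
    flat = np.full((4, 2), 0.5)
    assert roc_auc(truth, flat)["per_class"] == pytest.approx([0.5, 0.5])


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(11)
    truth = rng.integers(0, 2, 40)
    truth[:2] = [0, 1]
    score = rng.random(40)
    probs = np.c_[1 - score, score]
    a1 = roc_auc(truth, probs)["per_class"][1]
    warped = score**3  # strictly monotone
    probs2 = np.c_[1 - warped, warped]
    # renormalize rows to stay stochastic
    probs2 = probs2 / probs2.sum(axis=1, keepdims=True)
    a2 = roc_auc(truth, probs2)["per_class"][1]
    assert a1 == pytest.approx(a2)


def test_auc_missing_class_reported_nan():
    with pytest.warns(RuntimeWarning):
        res = roc_auc([0, 0, 1, 1], np.full((4, 3), 1 / 3))
    assert np.isnan(res["per_class"][2])


# --------------------------------------------------------------------
# full report
# --------------------------------------------------------------------
def test_report_composes_individual_metrics(rng):
    truth = rng.integers(0, 3, 45)
    truth[:3] = [0, 1, 2]
    raw = rng.random((45, 3))
    probs = raw / raw.sum(axis=1, keepdims=True)
    rep = report_from_predictions(truth, probs, ["a", "b", "c"])
    cm = confusion_matrix(truth, probs.argmax(axis=1), 3)
    assert np.array_equal(rep.confusion, cm)
    assert rep.accuracy == pytest.approx(basic_metrics(cm)["accuracy"])
    assert rep.micro_f1 == pytest.approx(micro_metrics(cm)["f1"])
    assert rep.macro_f1 == pytest.approx(macro_metrics(cm)["f1"])
    assert rep.macro_auc == pytest.approx(roc_auc(truth, probs)["macro"])


def test_perfect_predictions_give_all_100_percent():
    truth = np.array([0, 1, 2, 0, 1, 2])
    probs = np.eye(3)[truth] * 0.94 + 0.02
    rep = report_from_predictions(truth, probs, ["a", "b", "c"])
    frame = rep.to_frame(percent=True)
    assert (frame["value"] == 100.0).all()


def test_figure_helpers_write_files(tmp_path, rng):
    from sscnn.metrics import plot_confusion_matrix, plot_roc_curves

    cm = np.array([[10, 1], [2, 9]])
    plot_confusion_matrix(cm, ["a", "b"], tmp_path / "cm.png")
    truth = rng.integers(0, 2, 20)
    truth[:2] = [0, 1]
    raw = rng.random((20, 2))
    plot_roc_curves(truth, raw / raw.sum(axis=1, keepdims=True), ["a", "b"], tmp_path / "roc.png")
    assert (tmp_path / "cm.png").stat().st_size > 0
    assert (tmp_path / "roc.png").stat().st_size > 0


def test_percent_formatting_round_trip():
    truth = np.array([0, 1, 2, 0, 1, 2])
    probs = np.eye(3)[truth] * 0.94 + 0.02
    probs[0] = [0.02, 0.96, 0.02]  # one mistake -> accuracy 5/6
    rep = report_from_predictions(truth, probs, ["a", "b", "c"])
    frame = rep.to_frame(percent=True)
    assert frame.loc["Accuracy", "value"] == pytest.approx(round(rep.accuracy * 100, 2))
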