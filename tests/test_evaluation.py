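"""Confusion metrics, fixed-FPR thresholding, AUC/pAUC, CV protocol."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phosfuse import (
    PipelineConfig, confusion_metrics, evaluate, kfold_cv, roc_auc_pauc,
    subsample_ratio, threshold_at_fpr,
)


def mannwhitney_auc(scores, labels):
    """Brute-force pairwise comparison oracle: P(s+ > s-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_scores():
    scores = np.array([1.0] * 5 + [0.0] * 5)
    labels = np.array([1] * 5 + [0] * 5)
    r = confusion_metrics(scores, labels, 0.5)
    assert (r.tpr, r.tnr, r.acc, r.mcc) == (1, 1, 1, 1)
    assert (r.fnr, r.mcr) == (0, 0)


def test_inverted_scores_mcc_minus_one():
    scores = np.array([0.0] * 5 + [1.0] * 5)
    labels = np.array([1] * 5 + [0] * 5)
    assert confusion_metrics(scores, labels, 0.5).mcc == -1


def test_hand_computed_confusion_table():
    """TP=8, FN=2, TN=15, FP=5 evaluated against direct arithmetic."""
    scores = np.concatenate([np.ones(8), np.zeros(2), np.zeros(15), np.ones(5)])
    labels = np.concatenate([np.ones(10, int), np.zeros(20, int)])
    r = confusion_metrics(scores, labels, 0.5)
    assert (r.tp, r.fn, r.tn, r.fp) == (8, 2, 15, 5)
    assert r.tpr == pytest.approx(0.8)
    assert r.tnr == pytest.approx(0.75)
    assert r.acc == pytest.approx(23 / 30)
    assert r.mcr == pytest.approx(7 / 30)
    mcc = (8 * 15 - 5 * 2) / np.sqrt(10 * 20 * 13 * 17)
    assert r.mcc == pytest.approx(mcc, abs=1e-12)


def test_metric_identities_random(rng):
    for _ in range(20):
        scores = rng.random(50)
        labels = (rng.random(50) < 0.4).astype(int)
        if labels.sum() in (0, 50):
            continue
        r = confusion_metrics(scores, labels, float(rng.random()))
        assert r.tpr + r.fnr == pytest.approx(1.0, abs=1e-12)
        assert r.tnr + r.fpr == pytest.approx(1.0, abs=1e-12)
        assert r.acc + r.mcr == pytest.approx(1.0, abs=1e-12)
        assert -1 <= r.mcc <= 1


def test_single_class_error():
    with pytest.raises(ValueError, match="both classes"):
        confusion_metrics([0.1, 0.2], [1, 1], 0.5)


def test_threshold_at_fpr_enumerated():
    """10 distinct-score negatives at cap 0.20: at most 2 score above threshold."""
    neg = np.linspace(0.05, 0.95, 10)
    pos = np.array([0.5, 0.6, 0.9])
    scores = np.concatenate([pos, neg])
    labels = np.array([1] * 3 + [0] * 10)
    t = threshold_at_fpr(scores, labels, 0.20)
    assert np.sum(neg > t) <= 2
    # smallest feasible threshold: one notch lower breaks the cap
    lower = np.sort(np.unique(scores))
    below = lower[lower < t]
    if len(below):
        assert np.sum(neg > below[-1]) > 2


def test_threshold_perfect_separation_and_full_cap():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    t = threshold_at_fpr(scores, labels, 0.20)
    assert np.sum(scores[labels == 0] > t) == 0
    assert np.sum(scores[labels == 1] > t) == 2  # FPR 0, TPR 1
    t1 = threshold_at_fpr(scores, labels, 1.0)
    assert t1 < scores.min()
    assert confusion_metrics(scores, labels, t1).tpr == 1.0


def test_threshold_tie_grouping_never_exceeds_cap():
    # 5 negatives share the score 0.7: admitting one admits all
    scores = np.array([0.9, 0.8] + [0.7] * 5 + [0.1] * 5)
    labels = np.array([1, 1] + [0] * 10)
    t = threshold_at_fpr(scores, labels, 0.30)
    fpr = np.mean(scores[labels == 0] > t)
    assert fpr <= 0.30
    assert fpr == 0.0  # the tied block (5/10 = 0.5) cannot be split


def test_threshold_bad_cap():
    with pytest.raises(ValueError, match="fpr_cap"):
        threshold_at_fpr([0.1, 0.9], [0, 1], 0.0)


def test_auc_matches_mannwhitney_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(8, 40))
        labels = np.zeros(n, int)
        labels[:int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.random(n), 2)  # induce ties
        _, auc, _ = roc_auc_pauc(scores, labels)
        assert auc == pytest.approx(mannwhitney_auc(scores, labels), abs=1e-12)


def test_pauc_perfect_and_random():
    labels = np.array([1] * 50 + [0] * 50)
    perfect = np.concatenate([np.ones(50), np.zeros(50)])
    _, auc, pauc = roc_auc_pauc(perfect, labels, 0.20)
    assert auc == 1.0
    assert pauc == pytest.approx(0.20, abs=1e-12)

    rng = np.random.default_rng(0)
    big_labels = np.array([1] * 10000 + [0] * 10000)
    random_scores = rng.random(20000)
    _, auc_r, pauc_r = roc_auc_pauc(random_scores, big_labels, 0.20)
    assert auc_r == pytest.approx(0.5, abs=0.02)
    assert pauc_r == pytest.approx(0.02, abs=0.004)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=60),
       st.integers(0, 2 ** 31 - 1))
def test_pauc_at_cap_one_equals_auc(values, seed):
    scores = np.array(values)
    labels = np.random.default_rng(seed).integers(0, 2, len(scores))
    if labels.sum() in (0, len(labels)):
        labels[0], labels[-1] = 1, 0
    _, auc, pauc = roc_auc_pauc(scores, labels, fpr_cap=1.0)
    assert pauc == pytest.approx(auc, abs=1e-12)


def test_pauc_bounded_by_cap(rng):
    for _ in range(20):
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        labels[0], labels[1] = 1, 0
        _, _, pauc = roc_auc_pauc(scores, labels, 0.20)
        assert 0 <= pauc <= 0.20 + 1e-15


def test_evaluate_tnr_respects_cap(rng):
    scores = rng.random(300)
    labels = (rng.random(300) < 0.33).astype(int)
    r = evaluate(scores, labels, fpr_cap=0.20)
    assert r.tnr >= 0.80 - 1e-12


CV_CONFIG = PipelineConfig(hyper={"n_estimators": 40}, internal_cv_k=2)


def test_kfold_partition_and_ratio(small_windows):
    ws = subsample_ratio(small_windows, 2, seed=0)
    from sklearn.model_selection import StratifiedKFold
    y = ws.labels
    folds = list(StratifiedKFold(5, shuffle=True, random_state=0)
                 .split(np.zeros(len(y)), y))
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(len(y)))  # disjoint cover
    for _, te in folds:
        frac = y[te].mean()
        assert abs(frac - 1 / 3) < 0.02  # 1:2 ratio preserved per fold


def test_kfold_cv_runs_and_reports(small_windows):
    ws = subsample_ratio(small_windows, 2, seed=1)
    result = kfold_cv(ws, CV_CONFIG, k=3, seed=1)
    assert len(result.fold_reports) == 3
    s = result.summary()
    assert 0 <= s["auc"]["mean"] <= 1
    assert s["tnr"]["mean"] >= 0.80 - 1e-12  # fixed-FPR cap at 0.20
    for scheme in ("CKSAAP", "BINARY", "AAC"):
        assert len(result.scheme_auc[scheme]) == 3


def test_kfold_cv_class_too_small():
    from conftest import make_window
    from phosfuse import WindowSet
    ws = WindowSet([make_window("A" * 12 + "S" + "A" * 12, label=i % 2,
                                protein_id=f"p{i}") for i in range(6)])
    with pytest.raises(ValueError, match="at least k"):
        kfold_cv(ws, CV_CONFIG, k=5, seed=0)
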