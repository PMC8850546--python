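"""Fixed-FPR confusion metrics, ROC/AUC/pAUC, and the k-fold CV protocol.

The operating point is chosen by capping the empirical false positive rate
(default 0.20): the threshold is the smallest score cutoff whose FPR does not
exceed the cap, which maximizes TPR subject to the cap. Predicted positive
means ``score > threshold`` (strict); tied scores at the threshold are
grouped all-or-none so the cap is never exceeded.

pAUC is the unnormalized trapezoid area under the ROC curve over
FPR in [0, cap] (maximum = cap), with linear interpolation at the cap.

``kfold_cv`` runs the leakage-safe protocol: folds are ratio-stratified and
the *entire* pipeline — Kruskal–Wallis feature selection, backend training
and fusion-weight derivation — is refit on the training folds of each split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .model_fusion import FusionModel, PipelineConfig, train_fusion
from .types import WindowSet


@dataclass
class EvaluationReport:
    """Confusion metrics at a fixed-FPR threshold plus ROC/AUC/pAUC."""

    threshold: float
    tp: int
    fn: int
    tn: int
    fp: int
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    acc: float
    mcr: float
    mcc: float
    auc: float = float("nan")
    pauc: float = float("nan")
    fpr_cap: float = 0.20
    roc_points: list = field(default_factory=list)

    def metrics_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("threshold", "tpr", "tnr", "fpr", "fnr", "acc",
                          "mcr", "mcc", "auc", "pauc")}


@dataclass
class CVResult:
    """Per-fold reports plus mean and standard error per metric."""

    fold_reports: list
    scheme_auc: dict  # scheme -> list of per-fold single-backend AUCs
    k: int

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in self.fold_reports]))

    def se(self, metric: str) -> float:
        vals = [getattr(r, metric) for r in self.fold_reports]
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    def scheme_auc_mean(self, scheme: str) -> float:
        return float(np.mean(self.scheme_auc[scheme]))

    def summary(self) -> dict:
        out = {}
        for m in ("tpr", "tnr", "fnr", "fpr", "acc", "mcr", "mcc", "auc", "pauc"):
            out[m] = {"mean": self.mean(m), "se": self.se(m)}
        out["scheme_auc"] = {s: float(np.mean(v))
                             for s, v in self.scheme_auc.items()}
        return out


def _check_two_classes(labels: np.ndarray) -> None:
    if (labels == 1).sum() == 0 or (labels != 1).sum() == 0:
        raise ValueError("both classes must be present")


def confusion_metrics(scores, labels, threshold: float,
                      fpr_cap: float = 0.20) -> EvaluationReport:
    """All confusion-matrix metrics with predicted positive iff score > threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    tpr = tp / (tp + fn)
    fpr = fp / (tn + fp)
    tnr = tn / (tn + fp)
    fnr = fn / (tp + fn)
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    mcr = (fp + fn) / n
    denom = np.sqrt(float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0
    return EvaluationReport(threshold, tp, fn, tn, fp, tpr, tnr, fpr, fnr,
                            acc, mcr, float(mcc), fpr_cap=fpr_cap)


def threshold_at_fpr(scores, labels, fpr_cap: float = 0.20) -> float:
    """Smallest threshold whose empirical FPR <= cap (maximizing TPR).

    Candidate cutoffs are the distinct observed scores plus one value below
    the minimum; tied scores are grouped, so the cap is never exceeded.
    """
    if not 0 < fpr_cap <= 1:
        raise ValueError(f"fpr_cap must be in (0, 1], got {fpr_cap}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    neg = np.sort(scores[labels != 1])
    if len(neg) == 0:
        raise ValueError("no negatives: FPR cap is undefined")
    candidates = np.concatenate(([scores.min() - 1.0], np.unique(scores)))
    # FPR(t) = #(neg > t) / n_neg, non-increasing in t: return the first
    # (smallest) candidate satisfying the cap.
    n_neg = len(neg)
    for t in candidates:
        n_above = n_neg - np.searchsorted(neg, t, side="right")
        if n_above / n_neg <= fpr_cap:
            return float(t)
    return float(candidates[-1])  # unreachable: FPR at max score is 0


def roc_auc_pauc(scores, labels, fpr_cap: float = 0.20):
    """ROC points, trapezoid AUC, and unnormalized pAUC over FPR in [0, cap]."""
    if not 0 < fpr_cap <= 1:
        raise ValueError(f"fpr_cap must be in (0, 1], got {fpr_cap}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    mask = fpr <= fpr_cap
    fpr_p = np.append(fpr[mask], fpr_cap)
    tpr_p = np.append(tpr[mask], np.interp(fpr_cap, fpr, tpr))
    pauc = float(np.trapezoid(tpr_p, fpr_p))
    return list(zip(fpr.tolist(), tpr.tolist())), auc, pauc


def evaluate(scores, labels, fpr_cap: float = 0.20,
             threshold: float | None = None) -> EvaluationReport:
    """Full report: fixed-FPR confusion metrics plus ROC/AUC/pAUC."""
    if threshold is None:
        threshold = threshold_at_fpr(scores, labels, fpr_cap)
    report = confusion_metrics(scores, labels, threshold, fpr_cap)
    roc, auc, pauc = roc_auc_pauc(scores, labels, fpr_cap)
    report.auc, report.pauc, report.roc_points = auc, pauc, roc
    return report


def kfold_cv(ws: WindowSet, config: PipelineConfig | None = None, k: int = 5,
             seed: int = 0) -> CVResult:
    """Ratio-stratified k-fold CV refitting the whole pipeline per fold.

    Each fold preserves the positive:negative ratio of *ws*. For every
    split the pipeline (feature selection, backend training, weight
    derivation) is refit on the k-1 training folds only; the held-out fold
    is scored and summarized at the fixed-FPR operating point.
    """
    config = config or PipelineConfig()
    y = ws.labels
    _check_two_classes(y)
    counts = np.bincount(y)
    if counts[counts > 0].min() < k:
        raise ValueError(f"each class must have at least k={k} windows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    reports = []
    scheme_auc = {scheme: [] for scheme in ("CKSAAP", "BINARY", "AAC")}
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        fold_seed = int(rng.integers(2 ** 31))
        model = train_fusion(ws.subset(train_idx), config, seed=fold_seed)
        test_ws = ws.subset(test_idx)
        y_test = test_ws.labels
        fused = model.score_windows(test_ws)
        reports.append(evaluate(fused, y_test, config.fpr_cap))
        for scheme in scheme_auc:
            s = model.score_scheme(scheme, test_ws)
            scheme_auc[scheme].append(roc_auc_pauc(s, y_test, config.fpr_cap)[1])
    return CVResult(reports, scheme_auc, k)
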