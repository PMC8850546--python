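"""Per-encoder classifier backends and weighted score fusion.

One classifier is trained per encoding scheme (CKSAAP, binary, AAC) on its
KW-selected features. The fused score of a window is the convex combination

    score = w1 * f(CKSAAP) + w2 * f(Binary) + w3 * f(AAC),   w1+w2+w3 = 1,

with weights proportional to each scheme's standalone performance (internal
cross-validated AUC by default; training-set performance or manual weights
are available via config). Backend families are Random Forest (500 trees),
AdaBoost (100 stumps) and an RBF-kernel SVM whose decision values are mapped
to [0, 1] by Platt calibration so the convex combination is well defined
across families. Training is delegated to scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__
from .encoders import SCHEMES, FeatureMatrix, encode_matrix, feature_names_for
from .feature_select import select_top_n
from .types import PeptideWindow, WindowSet

_DEFAULT_HYPER = {
    "RF": {"n_estimators": 500, "n_jobs": 1},
    "ADA": {"n_estimators": 100},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}


@dataclass
class PipelineConfig:
    """All tunables of the window-to-score pipeline.

    Defaults mirror the recommended operating point: 25-residue windows
    (w=12), kmax=5, top 1500/2646 CKSAAP and 400/504 binary features, AAC
    passed through unselected, RF backends, CV-derived fusion weights, and a
    fixed-FPR operating point at 0.20.
    """

    w: int = 12
    kmax: int = 5
    top_n_cksaap: int = 1500
    top_n_binary: int = 400
    top_n_aac: int | None = None
    family: str = "RF"
    hyper: dict = field(default_factory=dict)
    weight_mode: str = "cv"  # "cv" | "train" | "manual"
    weight_metric: str = "auc"  # "auc" | "pauc" | "acc"
    manual_weights: tuple | None = None
    internal_cv_k: int = 3
    fpr_cap: float = 0.20

    def top_n_for(self, scheme: str) -> int | None:
        return {"CKSAAP": self.top_n_cksaap, "BINARY": self.top_n_binary,
                "AAC": self.top_n_aac}[scheme]


@dataclass
class ClassifierBackend:
    """A fitted per-scheme classifier with its selected-feature provenance."""

    family: str
    scheme: str
    estimator: object
    feature_names: list
    feature_indices: np.ndarray
    encoder_params: dict

    def score(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability-like score in [0, 1] per row."""
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class FusionModel:
    """Three per-scheme backends plus normalized fusion weights."""

    backends: dict
    weights: tuple
    config: PipelineConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,):
            raise ValueError("weights must be a length-3 tuple")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must be >= 0 and sum to 1, got {tuple(w)}")

    def _scheme_matrix(self, ws: WindowSet, scheme: str) -> np.ndarray:
        backend = self.backends[scheme]
        fm = encode_matrix(ws, scheme, kmax=self.config.kmax)
        idx = backend.feature_indices
        if len(idx) and idx.max() >= len(fm.names):
            raise ValueError(
                f"feature-name mismatch for {scheme}: encoder parameters do "
                f"not match the model's training configuration"
            )
        names = [fm.names[i] for i in idx]
        if names != list(backend.feature_names):
            raise ValueError(
                f"feature-name mismatch for {scheme}: encoder parameters do "
                f"not match the model's training configuration"
            )
        return fm.X[:, idx]

    def score_scheme(self, scheme: str, ws: WindowSet) -> np.ndarray:
        """Scores of one backend over a window set."""
        return self.backends[scheme].score(self._scheme_matrix(ws, scheme))

    def score_windows(self, ws: WindowSet) -> np.ndarray:
        """Fused scores (convex combination of the three backend scores)."""
        fused = np.zeros(len(ws))
        for weight, scheme in zip(self.weights, SCHEMES):
            if weight > 0:
                fused += weight * self.score_scheme(scheme, ws)
            # zero-weight backends are skipped: they cannot change the score
        return fused


def train_backend(fm: FeatureMatrix, labels, family: str = "RF",
                  hyper: dict | None = None, seed: int = 0) -> ClassifierBackend:
    """Fit one classifier family on a (selected) feature matrix."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 windows per class")
    est = make_estimator(family, hyper, seed)
    est.fit(fm.X, y)
    full_names = feature_names_for(fm.scheme, fm.params.get("w", 0),
                                   fm.params.get("kmax", 5))
    name_pos = {name: i for i, name in enumerate(full_names)}
    indices = np.array([name_pos[name] for name in fm.names], dtype=int)
    return ClassifierBackend(family.upper(), fm.scheme, est, list(fm.names),
                             indices, dict(fm.params))


def make_estimator(family: str, hyper: dict | None = None, seed: int = 0):
    family = family.upper()
    if family not in _DEFAULT_HYPER:
        raise ValueError(f"unknown classifier family {family!r}")
    params = dict(_DEFAULT_HYPER[family])
    params.update(hyper or {})
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "ADA":
        return AdaBoostClassifier(random_state=seed, **params)
    # Platt-style sigmoid calibration maps SVM decision values into [0, 1]
    # so the fusion's convex combination is well defined across families
    return CalibratedClassifierCV(SVC(random_state=seed, **params),
                                  method="sigmoid", cv=3, ensemble=False)


def derive_weights(perf_cksaap: float, perf_binary: float,
                   perf_aac: float) -> tuple[float, float, float]:
    """Fusion weights proportional to per-scheme standalone performance."""
    perfs = np.array([perf_cksaap, perf_binary, perf_aac], dtype=float)
    if (perfs <= 0).any():
        raise ValueError(f"all performances must be > 0, got {tuple(perfs)}")
    w = perfs / perfs.sum()
    return float(w[0]), float(w[1]), float(w[2])


def _perf_score(scores: np.ndarray, y: np.ndarray, metric: str,
                fpr_cap: float) -> float:
    if metric == "auc":
        return float(roc_auc_score(y, scores))
    from .evaluation import confusion_metrics, roc_auc_pauc, threshold_at_fpr
    if metric == "pauc":
        return roc_auc_pauc(scores, y, fpr_cap)[2]
    if metric == "acc":
        thr = threshold_at_fpr(scores, y, fpr_cap)
        return confusion_metrics(scores, y, thr).acc
    raise ValueError(f"unknown weight metric {metric!r}")


def _internal_cv_perf(fm: FeatureMatrix, y: np.ndarray, config: PipelineConfig,
                      seed: int) -> float:
    skf = StratifiedKFold(n_splits=config.internal_cv_k, shuffle=True,
                          random_state=seed)
    perfs = []
    base = make_estimator(config.family, config.hyper, seed)
    for tr, te in skf.split(fm.X, y):
        est = clone(base)
        est.fit(fm.X[tr], y[tr])
        perfs.append(_perf_score(est.predict_proba(fm.X[te])[:, 1], y[te],
                                 config.weight_metric, config.fpr_cap))
    return float(np.mean(perfs))


def train_fusion(ws: WindowSet, config: PipelineConfig | None = None,
                 seed: int = 0) -> FusionModel:
    """Train the full three-encoder fusion model on a window set.

    Per scheme: encode, select the top-N features by Kruskal–Wallis rank,
    fit the configured backend, and measure standalone performance for the
    fusion weights (internal stratified CV by default). Requested top-N
    larger than the scheme's dimensionality is clipped (relevant only for
    non-default window sizes).
    """
    config = config or PipelineConfig()
    y = ws.labels
    backends = {}
    perfs = []
    for i, scheme in enumerate(SCHEMES):
        fm = encode_matrix(ws, scheme, kmax=config.kmax)
        top_n = config.top_n_for(scheme)
        if top_n is not None:
            fm, _ = select_top_n(fm, y, min(top_n, fm.X.shape[1]))
        if config.weight_mode == "cv":
            perfs.append(_internal_cv_perf(fm, y, config, seed + i))
        backends[scheme] = train_backend(fm, y, config.family, config.hyper,
                                         seed + i)
        if config.weight_mode == "train":
            perfs.append(_perf_score(backends[scheme].score(fm.X), y,
                                     config.weight_metric, config.fpr_cap))
    if config.weight_mode == "manual":
        if config.manual_weights is None:
            raise ValueError("weight_mode='manual' requires manual_weights")
        total = float(np.sum(config.manual_weights))
        weights = tuple(float(v) / total for v in config.manual_weights)
        metadata = {"seed": seed}
    else:
        weights = derive_weights(*perfs)
        metadata = {"seed": seed,
                    "scheme_performance": dict(zip(SCHEMES, perfs)),
                    "weight_metric": config.weight_metric}
    metadata["n1"], metadata["n2"] = ws.n1, ws.n2
    return FusionModel(backends, weights, config, metadata)


def fuse_scores(model: FusionModel, window: PeptideWindow) -> float:
    """Fused score of a single window."""
    return float(model.score_windows(WindowSet([window]))[0])


def save_model(model: FusionModel, path) -> None:
    """Persist a fusion model (versioned joblib archive)."""
    payload = {
        "format_version": 1,
        "tool_version": __version__,
        "config": asdict(model.config),
        "weights": model.weights,
        "metadata": model.metadata,
        "backends": {
            scheme: {
                "family": b.family,
                "estimator": b.estimator,
                "feature_names": b.feature_names,
                "feature_indices": b.feature_indices,
                "encoder_params": b.encoder_params,
            }
            for scheme, b in model.backends.items()
        },
    }
    joblib.dump(payload, path)


def load_model(path) -> FusionModel:
    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError(f"unsupported model file version in {path}")
    config = PipelineConfig(**payload["config"])
    backends = {
        scheme: ClassifierBackend(d["family"], scheme, d["estimator"],
                                  d["feature_names"],
                                  np.asarray(d["feature_indices"]),
                                  d["encoder_params"])
        for scheme, d in payload["backends"].items()
    }
    return FusionModel(backends, tuple(payload["weights"]), config,
                       payload["metadata"])
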