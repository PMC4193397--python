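"""Classifier stack: confusion-matrix metrics, ROC/AUC, mRMR feature
selection, RBF-SVM training under stratified five-fold cross-validation, and
calibrated scored prediction.

The trained model serializes to a single JSON container (arrays included) and
its decision function is recomputed from the stored arrays at predict time, so
models survive environment changes and are text-only artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .core_io import ProteinRecord
from .curation import AGGREGATION_PRONE, LabeledSet
from .features import FeatureSpec, default_spec, extract_matrix

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must total >= 1")


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC from a confusion matrix.

    Acc = (TP+TN)/(TP+TN+FP+FN); Sn = TP/(TP+FN); Sp = TN/(FP+TN);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP)), with MCC = 0
    when the denominator vanishes. Sn is an error when TP+FN = 0.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no positive examples (TP+FN=0)")
    sn = tp / (tp + fn)
    sp = tn / (fp + tn) if (fp + tn) > 0 else float("nan")
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    if denom == 0:
        logger.warning("MCC denominator zero; reporting MCC = 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return {"Acc": acc, "Sn": sn, "Sp": sp, "MCC": float(mcc)}


def roc_auc(scores: Sequence[float], truth: Sequence[bool]) -> tuple[np.ndarray, float]:
    """ROC curve points and AUC.

    AUC is computed as the Mann-Whitney U statistic divided by n+ * n-, with
    ties counted 1/2 (rank formulation). The curve is swept over the distinct
    score thresholds, highest first.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    order = np.argsort(-scores, kind="mergesort")
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth)
    fps = np.cumsum(~sorted_truth)
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    curve = np.column_stack(
        [np.r_[0.0, fps[distinct] / n_neg], np.r_[0.0, tps[distinct] / n_pos]]
    )
    return curve, float(auc)


# --------------------------------------------------------------------------
# mRMR feature selection
# --------------------------------------------------------------------------


def discretize_equal_frequency(x: np.ndarray, bins: int = 5) -> np.ndarray:
    """Equal-frequency binning of a continuous vector into integer codes."""
    quantiles = np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(quantiles, x, side="left")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two discrete code vectors, plug-in estimate."""
    a = np.asarray(a)
    b = np.asarray(b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float((joint[mask] * np.log(joint[mask] / (pa @ pb)[mask])).sum())


def mrmr_select(X: np.ndarray, y: np.ndarray, k: int, bins: int = 5) -> list[int]:
    """Greedy mRMR (MID criterion) over equal-frequency-discretized features.

    The first feature maximizes relevance I(f; y); each subsequent pick
    maximizes I(f; y) - mean_{s in selected} I(f; s).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("label vector is constant")
    n_features = X.shape[1]
    if not 1 <= k <= n_features:
        raise ValueError(f"k={k} out of range for {n_features} features")
    codes = np.column_stack(
        [discretize_equal_frequency(X[:, j], bins) for j in range(n_features)]
    )
    relevance = np.array([mutual_information(codes[:, j], y) for j in range(n_features)])
    selected: list[int] = [int(np.argmax(relevance))]
    redundancy = np.zeros(n_features)
    pairwise_cache: dict[tuple[int, int], float] = {}

    def mi_pair(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pairwise_cache:
            pairwise_cache[key] = mutual_information(codes[:, i], codes[:, j])
        return pairwise_cache[key]

    while len(selected) < k:
        last = selected[-1]
        for j in range(n_features):
            redundancy[j] += mi_pair(j, last)
        score = relevance - redundancy / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


# --------------------------------------------------------------------------
# training / prediction
# --------------------------------------------------------------------------

DEFAULT_GRID = {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 0.01]}


@dataclass(frozen=True)
class Prediction:
    protein_id: str
    positive: bool
    confidence: float


@dataclass
class TrainedClassifier:
    """RBF-SVM with standardization, sigmoid calibration and provenance.

    ``confidence = 1 / (1 + exp(-calibration_slope * decision))`` so that a
    decision value of exactly 0 always maps to confidence 0.5 and the class
    call equals ``confidence >= 0.5``.
    """

    spec: FeatureSpec
    positive_label: str
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    class_weight: dict[int, float] | None
    calibration_slope: float
    cv_report: dict
    seed: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """RBF decision function recomputed from the stored arrays."""
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        sq = (
            (Z**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        kernel = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return kernel @ self.dual_coef + self.intercept

    def predict_records(self, proteins: Sequence[ProteinRecord]) -> list[Prediction]:
        _, X = extract_matrix(proteins, self.spec)
        return self.predict_matrix([p.id for p in proteins], X)

    def predict_matrix(self, ids: Sequence[str], X: np.ndarray) -> list[Prediction]:
        decisions = self.decision_values(X)
        conf = 1.0 / (1.0 + np.exp(-self.calibration_slope * decisions))
        return [
            Prediction(protein_id=pid, positive=bool(c >= 0.5), confidence=float(c))
            for pid, c in zip(ids, conf)
        ]

    # ---- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "aggprop-svm-1",
            "spec": json.loads(self.spec.to_json()),
            "spec_digest": self.spec.digest(),
            "positive_label": self.positive_label,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "class_weight": (
                {str(k): v for k, v in self.class_weight.items()}
                if self.class_weight
                else None
            ),
            "calibration_slope": self.calibration_slope,
            "cv_report": self.cv_report,
            "seed": self.seed,
        }
        return json.dumps(payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        if d.get("format") != "aggprop-svm-1":
            raise ValueError("unrecognized model container format")
        spec = FeatureSpec.from_json(json.dumps(d["spec"]))
        if spec.digest() != d["spec_digest"]:
            raise ValueError("feature spec digest mismatch in model container")
        return cls(
            spec=spec,
            positive_label=d["positive_label"],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            support_vectors=np.array(d["support_vectors"]),
            dual_coef=np.array(d["dual_coef"]),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            C=float(d["C"]),
            class_weight=(
                {int(k): v for k, v in d["class_weight"].items()}
                if d["class_weight"]
                else None
            ),
            calibration_slope=float(d["calibration_slope"]),
            cv_report=d["cv_report"],
            seed=int(d["seed"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        return cls.from_json(Path(path).read_text())


def _fit_svc(
    X: np.ndarray, y: np.ndarray, seed: int, class_weight, grid: dict
) -> SVC:
    search = GridSearchCV(
        SVC(kernel="rbf", class_weight=class_weight),
        grid,
        cv=StratifiedKFold(n_splits=3, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X, y)
    return search.best_estimator_


def _calibration_slope(decisions: np.ndarray, y: np.ndarray) -> float:
    """Zero-intercept logistic slope on decision values; forced positive.

    Maximum-likelihood fit of p = sigmoid(a * f) by Newton iterations. The
    zero intercept pins decision 0 to confidence 0.5.
    """
    f = np.asarray(decisions, dtype=float)
    t = np.asarray(y, dtype=float)
    a = 1.0
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-np.clip(a * f, -500, 500)))
        grad = float(np.dot(f, t - p))
        hess = float(np.dot(f * f, p * (1 - p)))
        if hess <= 1e-12:
            break
        step = grad / hess
        a += step
        if abs(step) < 1e-10:
            break
    if not np.isfinite(a) or a <= 0:
        logger.warning("calibration slope non-positive (%.3g); falling back to 1", a)
        a = 1.0
    return float(min(a, 1e3))


def train_cv_matrix(
    X: np.ndarray,
    y: np.ndarray,
    spec: FeatureSpec,
    positive_label: str,
    folds: int = 5,
    seed: int = 0,
    class_weight: str | dict | None = None,
    grid: dict | None = None,
) -> TrainedClassifier:
    """Train on a precomputed feature matrix; see :func:`train_cv`."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    grid = grid or DEFAULT_GRID
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_pred = np.empty_like(y)
    pooled_decision = np.empty(len(y), dtype=float)
    for train_idx, test_idx in skf.split(X, y):
        mean = X[train_idx].mean(axis=0)
        scale = X[train_idx].std(axis=0)
        scale[scale == 0] = 1.0
        Z_train = (X[train_idx] - mean) / scale
        Z_test = (X[test_idx] - mean) / scale
        clf = _fit_svc(Z_train, y[train_idx], seed, class_weight, grid)
        pooled_pred[test_idx] = clf.predict(Z_test)
        pooled_decision[test_idx] = clf.decision_function(Z_test)

    cm = ConfusionCounts(
        tp=int(((pooled_pred == 1) & (y == 1)).sum()),
        tn=int(((pooled_pred == 0) & (y == 0)).sum()),
        fp=int(((pooled_pred == 1) & (y == 0)).sum()),
        fn=int(((pooled_pred == 0) & (y == 1)).sum()),
    )
    report = metrics(cm)
    _, auc = roc_auc(pooled_decision, y == 1)
    report["AUC"] = auc
    report["confusion"] = {"TP": cm.tp, "TN": cm.tn, "FP": cm.fp, "FN": cm.fn}
    report["folds"] = folds

    # final refit on all data
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    clf = _fit_svc(Z, y, seed, class_weight, grid)
    gamma = clf._gamma if hasattr(clf, "_gamma") else clf.gamma
    slope = _calibration_slope(clf.decision_function(Z), y)
    cw = None
    if class_weight == "balanced":
        n = len(y)
        cw = {c: n / (2 * counts[c]) for c in (0, 1)}
    elif isinstance(class_weight, dict):
        cw = class_weight
    return TrainedClassifier(
        spec=spec,
        positive_label=positive_label,
        scaler_mean=mean,
        scaler_scale=scale,
        support_vectors=Z[clf.support_],
        dual_coef=clf.dual_coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        gamma=float(gamma),
        C=float(clf.C),
        class_weight=cw,
        calibration_slope=slope,
        cv_report=report,
        seed=seed,
    )


def train_cv(
    data: LabeledSet,
    spec: FeatureSpec | None = None,
    positive_label: str = AGGREGATION_PRONE,
    negative_label: str | None = None,
    folds: int = 5,
    seed: int = 0,
    class_weight: str | dict | None = None,
) -> TrainedClassifier:
    """Stratified k-fold CV training of the RBF-SVM on a curated LabeledSet.

    Standardization is fit on training folds only; the metric report pools the
    held-out confusion counts across folds (single confusion matrix); the final
    model is refit on all data. Use ``class_weight='balanced'`` for the
    imbalanced GroEL-obligate task.
    """
    if spec is None:
        spec = default_spec()
    if negative_label is None:
        labels_present = {lr.label for lr in data.records}
        negatives = labels_present - {positive_label}
        if len(negatives) != 1:
            raise ValueError(
                f"cannot infer negative label from classes {sorted(labels_present)}"
            )
        negative_label = negatives.pop()
    records = [
        lr for lr in data.records if lr.label in (positive_label, negative_label)
    ]
    y = np.array([1 if lr.label == positive_label else 0 for lr in records])
    _, X = extract_matrix([lr.record for lr in records], spec)
    return train_cv_matrix(
        X, y, spec, positive_label, folds=folds, seed=seed, class_weight=class_weight
    )


def predict(
    m: TrainedClassifier,
    proteins: Sequence[ProteinRecord],
    spec: FeatureSpec | None = None,
) -> list[Prediction]:
    """Scored predictions for a batch of proteins.

    If ``spec`` is given its digest must match the model's training spec.
    """
    if spec is not None and spec.digest() != m.spec.digest():
        raise ValueError("feature spec mismatch between model and extraction")
    return m.predict_records(proteins)
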